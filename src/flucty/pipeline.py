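"""End-to-end pipeline orchestration: simulate → analyze → report.

A :class:`RunConfig` (usually loaded from YAML) names the stages to run
and their parameters.  All randomness flows from the single config seed
through named per-stage substreams, so re-running the same config + seed
reproduces every deterministic output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import brightness, crosscorr, io, phasor, puncta, rics, simkit
from .types import (
    BeamProfile,
    PunctaSimSpec,
    RasterScanStack,
    ScanGeometry,
    SpeciesSpec,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("flucty")

_KNOWN_STAGES = {
    "simulate",
    "rics",
    "nb",
    "pch",
    "phasor",
    "ccrics",
    "puncta",
}
_KNOWN_TOP = _KNOWN_STAGES | {"seed", "output_dir", "input", "beam"}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage name → parameter dict; unknown stage or
    top-level keys are rejected so typos fail loudly rather than silently
    running defaults.
    """

    seed: int = 0
    output_dir: Path = Path("flucty_out")
    input: str | None = None
    beam: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_TOP
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = {k: dict(d[k] or {}) for k in _KNOWN_STAGES if k in d}
        return cls(
            seed=int(d.get("seed", 0)),
            output_dir=Path(d.get("output_dir", "flucty_out")),
            input=d.get("input"),
            beam=dict(d.get("beam") or {}),
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "input": self.input,
            "beam": self.beam,
            **self.stages,
        }

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed derived from the master seed."""
        h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return int(np.random.SeedSequence([self.seed, h]).generate_state(1)[0] % (2**31 - 1))


def _beam(cfg: RunConfig) -> BeamProfile:
    return BeamProfile(**cfg.beam) if cfg.beam else BeamProfile()


def _simulate(cfg: RunConfig, params: dict, outdir: Path) -> dict:
    kind = params.get("kind", "stack")
    seed = cfg.stage_seed("simulate")
    beam = _beam(cfg)
    result: dict = {"kind": kind, "seed": seed}
    if kind in ("stack", "two-channel"):
        geom = ScanGeometry(**params.get("geometry", {}))
        species = [SpeciesSpec(**s) for s in params.get("species", [])]
        if kind == "stack":
            st = simkit.simulate_raster_stack(species, beam, geom, seed)
            io.write_stack(st, outdir / "stack.tif")
            result["files"] = ["stack.tif", "stack.yaml"]
        else:
            g, r = simkit.simulate_two_channel_stack(
                species[0], species[1],
                float(params.get("bound_fraction", 0.5)), beam, geom, seed,
            )
            io.write_stack(g, outdir / "green.tif")
            io.write_stack(r, outdir / "red.tif")
            result["files"] = ["green.tif", "red.tif"]
    elif kind == "tirf":
        geom = ScanGeometry(**params.get("geometry", {}))
        spec = PunctaSimSpec(**params.get("puncta", {}))
        st = simkit.simulate_tirf_series(
            spec, geom, params.get("background", 10.0), seed
        )
        io.write_stack(st, outdir / "tirf.tif")
        result["files"] = ["tirf.tif", "tirf.yaml"]
    elif kind == "trace":
        species = [SpeciesSpec(**s) for s in params.get("species", [])]
        tr = simkit.simulate_point_trace(
            species, beam,
            float(params.get("bin_time", 2e-5)),
            float(params.get("duration", 10.0)),
            seed,
        )
        io.write_trace(tr, outdir / "trace.csv")
        result["files"] = ["trace.csv"]
    elif kind == "decay":
        d = simkit.simulate_decay(
            params.get("lifetimes", [2.95]),
            params.get("fractions", [1.0]),
            float(params.get("rep_rate", 80e6)),
            int(params.get("n_photons", 10**6)),
            seed,
        )
        io.write_decay(d, outdir / "decay.csv")
        result["files"] = ["decay.csv"]
    else:
        raise ValueError(f"unknown simulate kind {kind!r}")
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    ``simulate`` (if requested) runs first and later stages consume its
    outputs; each stage failure is recorded with context and independent
    stages continue.  Returns the report dict (also written to
    ``report.json`` in the output directory).
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    beam = _beam(config)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "stages": {},
    }

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
            report["stages"][name] = {"ok": True, "result": out}
        except Exception as exc:  # recorded, pipeline continues
            report["stages"][name] = {"ok": False, "error": f"{type(exc).__name__}: {exc}"}
        dt = time.perf_counter() - t0
        report["stages"].setdefault(name, {})["seconds"] = round(dt, 3)
        log.info("stage %-10s %.2fs params=%s", name,
                 dt, config.stages.get(name, {}))

    if "simulate" in config.stages:
        run_stage("simulate", lambda: _simulate(config, config.stages["simulate"], outdir))

    def load_stack(name: str = "stack.tif") -> RasterScanStack:
        if config.input:
            return io.read_stack(config.input)
        return io.read_stack(outdir / name)

    if "rics" in config.stages:
        p = config.stages["rics"]

        def _rics():
            st = load_stack()
            acf = rics.compute_spatial_acf(
                st, p.get("detrend_window", 10), p.get("max_lag")
            )
            fit = rics.fit_diffusion(acf, beam, st.geometry, p.get("components", 1))
            out = {
                "components_D": [c[0] for c in fit.components],
                "components_G0": [c[1] for c in fit.components],
                "offset": fit.offset,
                "chi2_reduced": fit.chi2_reduced,
                "success": fit.success,
            }
            if fit.success and fit.components[-1][1] > 0:
                est = rics.concentration_from_amplitude(fit, beam)
                out["concentration_nM"] = est.value
            np.savetxt(outdir / "acf.csv", acf.values, delimiter=",")
            return out

        run_stage("rics", _rics)

    if "nb" in config.stages:
        p = config.stages["nb"]

        def _nb():
            st = load_stack(p.get("file", "stack.tif"))
            bmap = brightness.nb_maps(st, p.get("dead_time"), beam)
            out = {
                "median_B": float(np.median(bmap.B_map)),
                "mean_epsilon_cpsm": bmap.summary_epsilon(),
            }
            if "epsilon_mono" in p:
                cls = brightness.classify_pixels(
                    bmap, p["epsilon_mono"], p.get("band_half_width", 0.5)
                )
                out.update(
                    pct_monomer=cls.pct_monomer,
                    pct_dimer=cls.pct_dimer,
                    pct_higher=cls.pct_higher,
                )
            return out

        run_stage("nb", _nb)

    if "pch" in config.stages:
        p = config.stages["pch"]

        def _pch():
            tr = io.read_trace(config.input or outdir / "trace.csv")
            fit = brightness.pch_fit(brightness.pch_histogram(tr), beam)
            return {
                "epsilon_cpsm": fit.epsilon,
                "n_bar": fit.n_bar,
                "chi2_reduced": fit.chi2_reduced,
                "degenerate": fit.degenerate,
            }

        run_stage("pch", _pch)

    if "phasor" in config.stages:

        def _phasor():
            d = io.read_decay(config.input or outdir / "decay.csv")
            pt = phasor.phasor_transform(d)
            lt = phasor.lifetime_from_phasor(pt)
            return {
                "g": pt.g, "s": pt.s,
                "tau_phase_ns": lt.tau_phase, "tau_mod_ns": lt.tau_mod,
            }

        run_stage("phasor", _phasor)

    if "ccrics" in config.stages:
        p = config.stages["ccrics"]

        def _cc():
            sg = io.read_stack(p.get("green", outdir / "green.tif"))
            sr = io.read_stack(p.get("red", outdir / "red.tif"))
            res = crosscorr.cross_correlation_analysis(
                sg, sr, beam, p.get("detrend_window", 10), p.get("max_lag")
            )
            return {
                "g0_green": res.g0_green,
                "g0_red": res.g0_red,
                "g0_cross": res.g0_cross,
                "fraction_green_bound_pct": res.fraction_green_bound,
                "clipped": res.clipped,
            }

        run_stage("ccrics", _cc)

    if "puncta" in config.stages:
        p = config.stages["puncta"]

        def _puncta():
            st = load_stack(p.get("file", "tirf.tif"))
            dets = puncta.detect_stack(
                st,
                tuple(p.get("scale_range", (0.1, 0.5))),
                p.get("threshold_sd", 5.0),
            )
            tracks = puncta.track_puncta(
                dets,
                p.get("max_link_distance", 3 * st.geometry.pixel_size),
                p.get("max_gap", 1),
                st.geometry.frame_time_s,
            )
            out = {
                "mean_detections_per_frame": float(np.mean([len(d) for d in dets])),
                "n_tracks": len(tracks),
            }
            try:
                out["residence"] = puncta.residence_stats(tracks, st.n_frames)
            except ValueError as exc:
                out["residence_error"] = str(exc)
            return out

        run_stage("puncta", _puncta)

    io.write_report(report, outdir / "report.json")
    return report
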