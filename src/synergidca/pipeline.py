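"""End-to-end reproducible pipeline: simulate -> render -> extract -> peaks -> compare.

The pipeline regenerates a full synthetic study: for each crossing scheme it
simulates replicate synergid pairs, optionally renders and re-extracts them
through the imaging chain, detects transients under both trace-relative
thresholds, and emits cohort statistics (pooled boxplot summaries, ANOVA and
Tukey HSD across schemes) plus a checksummed manifest.  Identical
configuration and seeds reproduce identical trace-level artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cohort import (CrossScheme, box_stats, one_way_anova, pool, rank_traces,
                     select_median_trace, tukey_hsd)
from .errors import ConfigError
from .extraction import ExtractionConfig, extract_traces
from .peaks import (AnalysisConfig, compute_prominence, find_local_maxima,
                    detect_transients, trace_summary)
from .presets import PRESET_NAMES, make_preset
from .scene import SceneConfig, render_stack
from .simulate import TraceSimConfig, simulate_synergid_pair
from .stack import write_stack
from .trace import CalciumTrace, write_trace_csv

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("synergidca")


class SchemeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    preset: str
    female: str = "wildtype"
    pollen: str = "wildtype"
    n_traces: int = Field(default=10, ge=1)

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v: str) -> str:
        if v not in PRESET_NAMES:
            raise ValueError(f"unknown preset {v!r}; expected one of {PRESET_NAMES}")
        return v


def _default_schemes() -> list[SchemeSpec]:
    return [
        SchemeSpec(label="wt_x_wt", preset="wildtype",
                   female="wildtype", pollen="wildtype"),
        SchemeSpec(label="ferlre_x_wt", preset="fer_lre_female",
                   female="fer_lre", pollen="wildtype"),
        SchemeSpec(label="wt_x_myb", preset="myb_pollen",
                   female="wildtype", pollen="myb97_101_120"),
        SchemeSpec(label="wt_x_lyrata", preset="interspecific_lyrata",
                   female="wildtype", pollen="A_lyrata"),
        SchemeSpec(label="wt_x_pumila", preset="interspecific_pumila",
                   female="wildtype", pollen="O_pumila"),
    ]


class SimSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    frame_interval_s: float = Field(default=10.0, gt=0)
    duration_min_s: float = Field(default=960.0, gt=0)
    duration_max_s: float = Field(default=3480.0, gt=0)
    pre_contact_frames: int = Field(default=6, ge=0)


class SceneSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    height: int = Field(default=64, ge=8)
    width: int = Field(default=96, ge=8)
    bleed_fraction: float = Field(default=0.1, ge=0, lt=1)
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    speckle_rate: float = Field(default=0.001, ge=0, lt=1)
    read_noise_sd: float = Field(default=2.0, ge=0)
    photon_scaling: float = Field(default=1.0, ge=0)


class ExtractionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bleed_coefficient: float | None = None   # None: use the scene's bleed fraction
    outlier_radius: int = Field(default=2, ge=1)
    outlier_threshold: float = 50.0
    despeckle_kernel: int = Field(default=3, ge=1)
    cfp_floor: float = Field(default=1.0, gt=0)
    drift_correction: bool = True


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    amplitude_multiplier: float = Field(default=1.1, gt=1)
    frequency_multiplier: float = Field(default=5.0, gt=1)
    min_separation_s: float = Field(default=0.0, ge=0)


class StatsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(default=0.05, gt=0, lt=1)
    posthoc: bool = True


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schemes: list[SchemeSpec] = Field(default_factory=_default_schemes)
    base_seed: int = 1
    render: bool = True
    sim: SimSettings = Field(default_factory=SimSettings)
    scene: SceneSettings = Field(default_factory=SceneSettings)
    extraction: ExtractionSettings = Field(default_factory=ExtractionSettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load, default and validate a YAML pipeline configuration.

    An absent or empty file yields the fully-defaulted configuration; any
    unknown key or out-of-range value raises :class:`ConfigError` listing
    each violation.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    try:
        cfg = PipelineConfig(**data)
    except Exception as exc:
        raise ConfigError(f"invalid pipeline configuration: {exc}") from exc
    log.info("validated config: %s", cfg.model_dump())
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def peaks_table(trace: CalciumTrace, analysis: AnalysisSettings) -> pd.DataFrame:
    """All candidate local maxima with prominences and retention flags."""
    maxima = find_local_maxima(trace)
    rows = []
    proms = []
    for idx in maxima:
        prom, lb, rb = compute_prominence(trace, int(idx))
        proms.append(prom)
        rows.append({"index": int(idx), "time_s": float(trace.time_s[idx]),
                     "height": float(trace.ratio[idx]), "prominence": prom,
                     "left_base": lb, "right_base": rb})
    df = pd.DataFrame(rows, columns=["index", "time_s", "height", "prominence",
                                     "left_base", "right_base"])
    m = min(proms) if proms else float("nan")
    df["retained_amplitude"] = df["prominence"] > analysis.amplitude_multiplier * m
    df["retained_frequency"] = df["prominence"] > analysis.frequency_multiplier * m
    return df


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage name."""
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return _Guard()


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic study and return the artifact manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    amp_cfg = AnalysisConfig(mode="amplitude",
                             multiplier=cfg.analysis.amplitude_multiplier,
                             min_separation_s=cfg.analysis.min_separation_s)
    freq_cfg = AnalysisConfig(mode="frequency",
                              multiplier=cfg.analysis.frequency_multiplier,
                              min_separation_s=cfg.analysis.min_separation_s)
    bleed_coeff = (cfg.extraction.bleed_coefficient
                   if cfg.extraction.bleed_coefficient is not None
                   else cfg.scene.bleed_fraction)
    ext_cfg = ExtractionConfig(
        bleed_coefficient=bleed_coeff,
        outlier_radius=cfg.extraction.outlier_radius,
        outlier_threshold=cfg.extraction.outlier_threshold,
        despeckle_kernel=cfg.extraction.despeckle_kernel,
        cfp_floor=cfg.extraction.cfp_floor,
        drift_correction=cfg.extraction.drift_correction,
    )

    cohort_traces: dict[str, list[CalciumTrace]] = {}
    for scheme in cfg.schemes:
        preset = make_preset(scheme.preset)
        scheme_dir = out / scheme.label
        scheme_dir.mkdir(exist_ok=True)
        cohort_traces[scheme.label] = []
        for rep in range(scheme.n_traces):
            seed = cfg.base_seed + rep
            rep_dir = scheme_dir / f"rep_{rep:02d}"
            rep_dir.mkdir(exist_ok=True)
            sim_cfg = TraceSimConfig(
                frame_interval_s=cfg.sim.frame_interval_s,
                duration_min_s=cfg.sim.duration_min_s,
                duration_max_s=cfg.sim.duration_max_s,
                pre_contact_frames=cfg.sim.pre_contact_frames,
                seed=seed)
            with _stage(f"simulate[{scheme.label}/rep{rep}]"):
                (left, truth_l), (right, truth_r) = simulate_synergid_pair(
                    preset, sim_cfg, female=scheme.female,
                    pollen=scheme.pollen, replicate=rep)
            log.info("scheme=%s rep=%d seed=%d frames=%d",
                     scheme.label, rep, seed, len(right))

            for side, truth in (("left", truth_l), ("right", truth_r)):
                p = rep_dir / f"transients_{side}.csv"
                pd.DataFrame({"time_s": truth.true_transient_times,
                              "amplitude": truth.true_amplitudes}).to_csv(
                    p, index=False)
                files.append(p)

            if cfg.render:
                scene = SceneConfig(
                    height=cfg.scene.height, width=cfg.scene.width,
                    bleed_fraction=cfg.scene.bleed_fraction,
                    drift_per_frame=tuple(cfg.scene.drift_per_frame),
                    speckle_rate=cfg.scene.speckle_rate,
                    read_noise_sd=cfg.scene.read_noise_sd,
                    photon_scaling=cfg.scene.photon_scaling)
                with _stage(f"render[{scheme.label}/rep{rep}]"):
                    stack, rois, _ = render_stack(left, right, scene, seed)
                stack_path = rep_dir / "stack.tiff"
                write_stack(stack, stack_path)
                roi_path = rep_dir / "rois.yaml"
                rois.write(roi_path)
                files += [stack_path, roi_path]
                with _stage(f"extract[{scheme.label}/rep{rep}]"):
                    traces, offsets = extract_traces(
                        stack, rois, ext_cfg,
                        contact_frame=cfg.sim.pre_contact_frames,
                        meta_by_label={"left": left.meta, "right": right.meta})
                if offsets is not None:
                    p = rep_dir / "offsets.csv"
                    pd.DataFrame(offsets, columns=["dx", "dy"]).to_csv(
                        p, index_label="frame")
                    files.append(p)
            else:
                traces = {"left": left, "right": right}

            for side, tr in traces.items():
                p = rep_dir / f"trace_{side}.csv"
                write_trace_csv(tr, p)
                files.append(p)
                with _stage(f"peaks[{scheme.label}/rep{rep}/{side}]"):
                    table = peaks_table(tr, cfg.analysis)
                table.to_csv(rep_dir / f"peaks_{side}.csv", index=False)
                files.append(rep_dir / f"peaks_{side}.csv")

            # the receptive (right) synergid represents the replicate in
            # cohort-level statistics
            cohort_traces[scheme.label].append(traces["right"])

        summaries = []
        for rep, tr in enumerate(cohort_traces[scheme.label]):
            s = trace_summary(detect_transients(tr, freq_cfg))
            s["replicate"] = rep
            summaries.append(s)
        p = scheme_dir / "trace_summaries.csv"
        pd.DataFrame(summaries).to_csv(p, index=False)
        files.append(p)

    # ---- cohort comparison across schemes -------------------------------
    schemes = {label: CrossScheme.from_traces(label, traces, amp_cfg, freq_cfg)
               for label, traces in cohort_traces.items()}

    cohort_rows = []
    ranked_rows = []
    pooled: dict[str, dict[str, np.ndarray]] = {"amplitudes": {}, "intervals": {}}
    for label, scheme in schemes.items():
        for what in ("amplitudes", "intervals"):
            values = pool(scheme, what)["value"].to_numpy()
            pooled[what][label] = values
            if values.size:
                bs = box_stats(values)
                cohort_rows.append({"scheme": label, "what": what,
                                    "n_traces": scheme.n_traces,
                                    "n_values": bs.n, **vars(bs)})
        order = rank_traces(scheme)
        ranked_rows.append({"scheme": label,
                            "ranked_traces": " ".join(map(str, order)),
                            "median_trace": select_median_trace(scheme)})
    p = out / "cohort_stats.csv"
    pd.DataFrame(cohort_rows).to_csv(p, index=False)
    files.append(p)
    p = out / "ranked_traces.csv"
    pd.DataFrame(ranked_rows).to_csv(p, index=False)
    files.append(p)

    stat_rows = []
    for what, groups in pooled.items():
        usable = {k: v for k, v in groups.items() if v.size >= 2}
        if len(usable) < 2:
            continue
        with _stage(f"anova[{what}]"):
            res = one_way_anova(usable, alpha=cfg.stats.alpha)
        stat_rows.append({"what": what, "test": "anova", "F": res.F,
                          "df_between": res.df_between,
                          "df_within": res.df_within, "p": res.p,
                          "significant": res.significant})
        if cfg.stats.posthoc:
            ph = tukey_hsd(usable, alpha=cfg.stats.alpha)
            for pair, diff, padj, rej in zip(ph.pairs, ph.mean_diffs,
                                             ph.p_adjusted, ph.reject):
                stat_rows.append({"what": what, "test": "tukey_hsd",
                                  "pair": f"{pair[0]} vs {pair[1]}",
                                  "mean_diff": diff, "p": padj,
                                  "significant": rej})
    p = out / "anova_posthoc.csv"
    pd.DataFrame(stat_rows).to_csv(p, index=False)
    files.append(p)

    manifest = {
        "config": cfg.model_dump(mode="json"),
        "files": {str(f.relative_to(out)): _sha256(f) for f in sorted(set(files))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
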