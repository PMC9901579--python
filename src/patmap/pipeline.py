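"""Full-pipeline orchestration: preprocess -> windows -> activation ->
wave fronts -> repolarization -> sources, with resolved-config emission.

Every run resolves all "auto" parameters to concrete values and records
them, so re-running with the emitted config reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .activation import (ActivationMatrix, DerivativeThreshold,
                         auto_derivative_threshold, build_activation_matrix)
from .phase import stack_upstroke_windows
from .preprocess import precondition_stack
from .repolarization import (RepolarizationConfig, erp_min_from_apd,
                             map_front_repolarization)
from .sources import (classify_front_sources, classify_repetitiveness,
                      conduction_vector_field, detect_activation_origins,
                      dynamic_map_stack, leading_front_conduction_fields)
from .stack import VoltageStack
from .wavefronts import (WaveFrontConfig, WaveFrontLabeling,
                         estimate_conduction_block_threshold, label_wavefronts,
                         wavefront_at_maps)

log = logging.getLogger("patmap")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults."""

    cutoff_hz: float = 60.0
    spatial_kernel: int = 3
    temporal_kernel: int = 3
    invert: bool = True
    min_segment_ms: float = 128.0
    fdr_q: float = 0.01
    deriv_threshold: float | None = None      # None -> automated FDR threshold
    valley_frac: float = 0.75
    theta_t_cb_ms: float | None = None        # None -> automated estimate
    n_short_stimuli: int = 3
    erp_min_ms: float | None = None           # None -> 0.8 x min basal APD
    repol_level_frac: float = 0.8
    apd_min_ms: float = 80.0
    apd_max_ms: float = 400.0
    repol_method: str = "amplitude_crossing"
    n_map_labels: int = 4                     # largest fronts to map fully
    classify_label: int | None = None         # None -> largest front
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    stack: VoltageStack
    window_mask: np.ndarray
    threshold: DerivativeThreshold
    matrix: ActivationMatrix
    labeling: WaveFrontLabeling
    wf_config: WaveFrontConfig
    erp_min_ms: float
    at_maps: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    rt_maps: dict[int, np.ndarray] = field(default_factory=dict)
    apd_maps: dict[int, np.ndarray] = field(default_factory=dict)
    repetitiveness: dict[int, object] = field(default_factory=dict)
    origins: dict[int, object] = field(default_factory=dict)
    classification: object | None = None
    resolved_config: dict = field(default_factory=dict)
    stage_log: list[dict] = field(default_factory=list)


def _stage(result: PipelineResult, name: str, t0: float, **counts) -> None:
    entry = {"stage": name, "elapsed_s": round(time.time() - t0, 3), **counts}
    result.stage_log.append(entry)
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(
    raw: np.ndarray | VoltageStack,
    config: PipelineConfig | None = None,
    mask: np.ndarray | None = None,
    dt_ms: float = 1.0,
    pitch_mm: float = 0.7,
    preconditioned: bool = False,
) -> PipelineResult:
    """Execute the full analysis chain on a raw (or preconditioned) stack."""
    cfg = config or PipelineConfig()
    t0 = time.time()
    if isinstance(raw, VoltageStack) and preconditioned:
        stack = raw
    else:
        data = raw.data if isinstance(raw, VoltageStack) else raw
        if isinstance(raw, VoltageStack):
            dt_ms, pitch_mm = raw.dt_ms, raw.pitch_mm
            mask = raw.mask if mask is None else mask
        stack = precondition_stack(
            data, cutoff_hz=cfg.cutoff_hz, spatial_kernel=cfg.spatial_kernel,
            temporal_kernel=cfg.temporal_kernel, dt_ms=dt_ms, pitch_mm=pitch_mm,
            mask=mask, invert=cfg.invert)

    window_mask = stack_upstroke_windows(stack, min_segment_ms=cfg.min_segment_ms)

    if cfg.deriv_threshold is not None:
        threshold = DerivativeThreshold(cfg.deriv_threshold, method="manual",
                                        fdr_q=cfg.fdr_q)
    else:
        threshold = auto_derivative_threshold(stack, window_mask, fdr_q=cfg.fdr_q)

    matrix = build_activation_matrix(stack, window_mask, threshold,
                                     valley_frac=cfg.valley_frac)

    if cfg.theta_t_cb_ms is not None:
        theta = cfg.theta_t_cb_ms
        theta_method = "manual"
    else:
        theta = estimate_conduction_block_threshold(
            matrix, cfg.n_short_stimuli, stack.nx, stack.ny)
        theta_method = "auto"

    repol_cfg = RepolarizationConfig(
        level_frac=cfg.repol_level_frac, apd_min_ms=cfg.apd_min_ms,
        apd_max_ms=cfg.apd_max_ms, method=cfg.repol_method)

    wf_cfg = WaveFrontConfig(theta_t_cb_ms=theta, erp_min_ms=cfg.erp_min_ms,
                             theta_method=theta_method)
    labeling = label_wavefronts(matrix, wf_cfg)

    result = PipelineResult(
        stack=stack, window_mask=window_mask, threshold=threshold,
        matrix=matrix, labeling=labeling, wf_config=wf_cfg, erp_min_ms=0.0)
    _stage(result, "preprocess", t0, frames=stack.nt,
           pixels=int(stack.mask.sum()))
    _stage(result, "windows", t0, windowed_frac=round(float(window_mask.mean()), 4))
    _stage(result, "threshold", t0, value=threshold.value, method=threshold.method)
    _stage(result, "activation", t0, events=len(matrix))
    _stage(result, "wavefronts", t0, labels=labeling.n_labels, theta_ms=theta)

    # largest fronts get full map treatment
    sizes = sorted(result.labeling.info,
                   key=lambda k: -result.labeling.info[k]["n_events"])
    mapped = sizes[:cfg.n_map_labels]
    for lab in mapped:
        result.at_maps[lab] = wavefront_at_maps(matrix, labeling, lab)
        rt, apd, _limits = map_front_repolarization(stack, labeling, lab, repol_cfg)
        result.rt_maps[lab] = rt
        result.apd_maps[lab] = apd
    _stage(result, "repolarization", t0, mapped_labels=len(mapped))

    # ERPmin: manual, or fallback 0.8 x minimum basal APD of the first front
    if cfg.erp_min_ms is not None:
        erp = cfg.erp_min_ms
        erp_method = "manual"
    else:
        basal = None
        for lab in sorted(result.apd_maps):
            finite = result.apd_maps[lab][np.isfinite(result.apd_maps[lab])]
            if finite.size:
                basal = float(finite.min())
                break
        if basal is None:
            raise RuntimeError("cannot resolve ERPmin: no APDs mapped; "
                               "set erp_min_ms in the config")
        erp = erp_min_from_apd(basal)
        erp_method = "auto"
    result.erp_min_ms = erp
    result.wf_config.erp_min_ms = erp
    result.wf_config.erp_method = erp_method

    for lab in mapped:
        result.repetitiveness[lab] = classify_repetitiveness(
            labeling, lab, erp, mask=stack.mask)
        result.origins[lab] = detect_activation_origins(
            labeling, lab, erp, stack.mask)
    _stage(result, "characterisation", t0, erp_min_ms=round(erp, 2),
           origins=sum(len(o.clusters) for o in result.origins.values()))

    # source classification of the probed (largest) front via dynamic maps
    probe = cfg.classify_label or (sizes[0] if sizes else None)
    if probe is not None:
        result.classification = classify_label_sources(result, probe)
        _stage(result, "sources", t0, label=probe,
               leading=result.classification.n_leading)

    result.resolved_config = dataclasses.asdict(cfg) | {
        "deriv_threshold": threshold.value,
        "theta_t_cb_ms": theta,
        "erp_min_ms": erp,
    }
    return result


def classify_label_sources(result: PipelineResult, label_id: int,
                           window_ms: tuple[float, float] | None = None):
    """Dynamic-map source classification of one front, aggregated over maps."""
    m = result.matrix
    sel = result.labeling.events_of(label_id)
    stack_maps = dynamic_map_stack(
        (m.x[sel], m.y[sel], m.t_ms[sel]), (result.stack.ny, result.stack.nx),
        window_ms)
    if label_id not in result.origins:
        result.origins[label_id] = detect_activation_origins(
            result.labeling, label_id, result.erp_min_ms, result.stack.mask)
    origins = result.origins[label_id]
    from .sources import SourceClassification, CLASS_NAMES

    per_point: dict = {}
    counts = {name: 0 for name in CLASS_NAMES}
    theta = result.wf_config.theta_t_cb_ms
    for dyn in stack_maps:
        vecs = conduction_vector_field(dyn.values, result.stack.pitch_mm,
                                       max_dt_ms=2 * theta)
        fields = leading_front_conduction_fields(
            dyn.values, vecs, result.wf_config.theta_t_cb_ms)
        cls = classify_front_sources(
            fields, origins, dyn.values, result.erp_min_ms,
            result.wf_config.theta_t_cb_ms, result.labeling, label_id,
            window_ms=(dyn.t_start_ms, dyn.t_end_ms + result.stack.dt_ms))
        for pt, classes in cls.per_point.items():
            per_point[(id(dyn), pt)] = classes
            for c in classes:
                counts[c] += 1
    total = sum(counts.values())
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return SourceClassification(per_point, counts, pct)


def write_artifacts(result: PipelineResult, outdir: str | Path) -> Path:
    """Write the standard artifact bundle of a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _put(name: str, path: Path) -> None:
        manifest[name] = path.name

    p = outdir / "resolved_config.json"
    p.write_text(json.dumps(result.resolved_config, indent=2))
    _put("resolved_config", p)

    p = pio.write_events_csv(result.matrix, outdir / "events.csv")
    _put("events", p)

    import pandas as pd

    lab_df = result.matrix.to_frame()
    lab_df["label"] = result.labeling.labels
    p = outdir / "labels.csv"
    lab_df.to_csv(p, index=False)
    _put("labels", p)

    for lab, (primary, secondary) in result.at_maps.items():
        p = pio.write_map_csv(primary, outdir / f"at_label{lab}.csv")
        _put(f"at_label{lab}", p)
        pio.render_isochrone_png(primary, outdir / f"at_label{lab}.png",
                                 title=f"pAT wave front #{lab}")
        if np.isfinite(secondary).any():
            pio.write_map_csv(secondary, outdir / f"at2_label{lab}.csv")
    for lab, rt in result.rt_maps.items():
        pio.write_map_csv(rt, outdir / f"rt_label{lab}.csv")
    for lab, apd in result.apd_maps.items():
        pio.write_map_csv(apd, outdir / f"apd_label{lab}.csv")

    rep = {
        str(lab): {"classification": r.classification,
                   "histogram": {str(k): v for k, v in r.histogram.items()}}
        for lab, r in result.repetitiveness.items()
    }
    p = outdir / "repetitiveness.json"
    p.write_text(json.dumps(rep, indent=2))
    _put("repetitiveness", p)

    rows = []
    for lab, oset in result.origins.items():
        for i, c in enumerate(oset.clusters):
            rows.append({"label": lab, "cluster": i, "type": c.kind,
                         "centroid_x": c.centroid[0], "centroid_y": c.centroid[1],
                         "beat_t_ms": c.beat_t_ms, "size": len(c.members)})
    p = outdir / "origins.csv"
    pd.DataFrame(rows, columns=["label", "cluster", "type", "centroid_x",
                                "centroid_y", "beat_t_ms", "size"]).to_csv(
        p, index=False)
    _put("origins", p)

    if result.classification is not None:
        p = outdir / "classification.json"
        p.write_text(json.dumps({
            "counts": result.classification.counts,
            "percentages": result.classification.percentages,
            "n_leading": result.classification.n_leading,
        }, indent=2))
        _put("classification", p)

    p = outdir / "run.log"
    p.write_text("\n".join(json.dumps(e) for e in result.stage_log) + "\n")
    _put("log", p)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
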