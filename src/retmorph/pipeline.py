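"""End-to-end orchestration: mask -> per-eye parameters -> cohort reports.

``measure_eye`` runs the full morphometry pipeline on one labeled mask and
returns the 28-parameter record (standard field abbreviations as
column names) plus the
per-bifurcation table.  ``run_stats`` assembles the cohort-level reports:
descriptives, sex-subgroup comparisons, disease-vs-control comparisons,
the Spearman correlation long table and an MSSI-severity ROC.

All outputs are deterministic given inputs, configuration and seed; CSV
outputs carry a metadata comment header (version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import caliber as cal
from . import geometry as geo
from .graph import assign_zones, build_graph, estimate_widths, skeletonize_class
from .mask import ARTERY, VEIN, DiscSpec, SegmentationMask, zone_annulus

logger = logging.getLogger(__name__)

#: output column order (per-eye record)
RMP_COLUMNS = [
    "SDa", "SDv", "CRAE", "CRVE", "VLD", "VAD", "AVR", "LDRa", "LDRv",
    "ODa", "ODv", "AAa", "AAv", "ARa", "ARv", "BAa", "BAv", "BCa", "BCv",
    "JEDa", "JEDv", "NFBa", "NFBv", "CTa", "CTv", "STa", "STv", "FrD",
]

BIF_COLUMNS = ["class", "row", "col", "zone", "d0", "d1", "d2",
               "theta1", "theta2", "BA", "AA", "BC", "AR", "OD", "JED"]


@dataclass
class PipelineConfig:
    """Tunable choices of the measurement and statistics layers."""

    aggregation: str = "mean"  # mean | median, for per-bifurcation parameters
    jed_sign: int = 1  # +1: JED = x - 3; -1 flips the convention
    percentile_method: str = "weighted"  # weighted (SPSS HAVERAGE) | nearest
    bootstrap_replicates: int = 2000
    seed: int = 0
    zone_bounds: tuple | None = None  # override ((name, lo, hi), ...) in dd units

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")
        if self.jed_sign not in (1, -1):
            raise ValueError("jed_sign must be +1 or -1")
        if self.percentile_method not in ("weighted", "nearest"):
            raise ValueError("percentile_method must be 'weighted' or 'nearest'")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _aggregate(values: list[float], how: str) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return float(np.median(vals) if how == "median" else np.mean(vals))


def measure_eye(
    mask: SegmentationMask,
    disc: DiscSpec,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, float | None], pd.DataFrame]:
    """Compute the 28 per-eye vascular parameters from a labeled mask.

    Returns (record, bifurcation table).  Parameters whose inputs are absent
    (e.g. no measurable zone-C bifurcation of a class) are None and become
    empty CSV cells.
    """
    config = config or PipelineConfig()
    bounds = config.zone_bounds
    scale = disc.scale_um_per_px or 1.0

    record: dict[str, float | None] = {c: None for c in RMP_COLUMNS}
    bif_rows: list[dict] = []
    skeletons: dict[int, np.ndarray] = {}
    graphs = {}

    for cls, suffix in ((ARTERY, "a"), (VEIN, "v")):
        skel = skeletonize_class(mask, cls)
        widths = estimate_widths(mask.class_mask(cls), skel)
        graph = assign_zones(build_graph(skel, widths, cls), disc, bounds)
        skeletons[cls], graphs[cls] = skel, graph

        calset = cal.six_largest(graph, zone="B")
        record["SD" + suffix] = (
            None if (sd := cal.diameter_sd(calset)) is None else sd * scale
        )
        eq = cal.knudtson_equivalent(calset)
        record["CRAE" if cls == ARTERY else "CRVE"] = None if eq is None else eq * scale
        if not calset.complete:
            logger.info("class %s: only %d zone-B caliber candidates", suffix, len(calset.calibers))

        record["LDR" + suffix] = cal.length_diameter_ratio(
            graph, geo.trunk_diameter, zone="C", aggregate=config.aggregation
        )

        per_bif = {k: [] for k in ("BA", "AA", "BC", "AR", "OD", "JED")}
        n_skipped = 0
        for node in graph.bifurcations():
            b = geo.measure_bifurcation(graph, node)
            if b is None:
                n_skipped += 1
                continue
            ba, aa, bc, ar = geo.branching_params(b)
            od = geo.optimality_deviation(b)
            jed = geo.junctional_exponent_deviation(b, sign=config.jed_sign)
            bif_rows.append(
                {"class": suffix, "row": b.position[0], "col": b.position[1],
                 "zone": b.zone, "d0": b.d0, "d1": b.d1, "d2": b.d2,
                 "theta1": b.theta1, "theta2": b.theta2,
                 "BA": ba, "AA": aa, "BC": bc, "AR": ar, "OD": od, "JED": jed}
            )
            if b.zone == "C":
                for k, v in zip(per_bif, (ba, aa, bc, ar, od, jed)):
                    per_bif[k].append(v)
        logger.info(
            "class %s: %d bifurcations measured, %d skipped",
            suffix, sum(len(v) for v in per_bif.values()) // 6, n_skipped,
        )
        for k, vals in per_bif.items():
            record[k + suffix] = _aggregate(vals, config.aggregation)

        record["NFB" + suffix] = float(geo.count_first_branches(graph, zone="C"))
        st, ct = geo.network_tortuosity(graph, zone="C")
        record["ST" + suffix], record["CT" + suffix] = st, ct

    vad, vld = cal.vessel_densities(mask, skeletons, disc, zone="C")
    record["VAD"], record["VLD"] = vad, vld
    record["AVR"] = cal.avr(record["CRAE"], record["CRVE"])

    from .mask import ZONE_BOUNDS

    annulus = zone_annulus(mask.shape, disc, "C", bounds or ZONE_BOUNDS)
    combined = (skeletons[ARTERY] | skeletons[VEIN]) & annulus
    record["FrD"] = geo.fractal_dimension(combined)

    return record, pd.DataFrame(bif_rows, columns=BIF_COLUMNS)


def _metadata_header(config: PipelineConfig) -> str:
    from . import __version__

    return f"# retmorph {__version__} config={config.hash()} seed={config.seed}\n"


def write_rmp_csv(records: list[dict], path: str | Path, config: PipelineConfig, ids=None) -> None:
    """Write per-eye records as CSV with the standard parameter abbreviations."""
    df = pd.DataFrame(records, columns=RMP_COLUMNS)
    if ids is not None:
        df.insert(0, "patient_id", ids)
    with open(path, "w") as fh:
        fh.write(_metadata_header(config))
        df.to_csv(fh, index=False)


def read_rmp_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_measure(
    mask_path: str | Path,
    disc_path: str | Path,
    out_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> tuple[dict, pd.DataFrame]:
    """File-level wrapper: read mask + disc, measure, optionally write CSVs."""
    from .mask import read_mask

    config = config or PipelineConfig()
    try:
        mask, disc = read_mask(mask_path, disc_path)
    except Exception as exc:
        raise RuntimeError(f"[read_mask] {exc}") from exc
    record, bif_table = measure_eye(mask, disc, config)
    if out_path is not None:
        out_path = Path(out_path)
        write_rmp_csv([record], out_path, config)
        bif_path = out_path.with_name(out_path.stem + "_bifurcations.csv")
        with open(bif_path, "w") as fh:
            fh.write(_metadata_header(config))
            bif_table.to_csv(fh, index=False)
    return record, bif_table


def run_stats(
    rmp_table: pd.DataFrame | None,
    cohort_table: pd.DataFrame,
    ctrl_rmp_table: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort-level report bundle.

    Pieces are produced when their inputs exist: descriptives and (with a
    ``sex`` column) the sex-subgroup table always; per-parameter group
    comparisons when a control table is supplied; the correlation long table
    and the MSSI-severity ROC when a per-patient parameter table is supplied.
    """
    from . import stats as st

    config = config or PipelineConfig()
    bundle: dict[str, pd.DataFrame] = {}
    bundle["demographics"] = st.cohort_summary(cohort_table, config.percentile_method)
    if "sex" in cohort_table.columns:
        bundle["gender"] = st.gender_subgroup_report(cohort_table, config.percentile_method)

    if rmp_table is not None:
        if "patient_id" in rmp_table.columns and "patient_id" in cohort_table.columns:
            unmatched = set(rmp_table["patient_id"]) - set(cohort_table["patient_id"])
            if unmatched:
                raise ValueError(f"parameter table ids missing from cohort: {sorted(unmatched)}")
        clin_cols = ["patient_id"] + [
            c for c in ("age", "onset_age", "alpha_gal", "lyso_gb3", "mssi",
                        "arwmc", "fazekas", "epvs", "mars", "lacuna", "svds", "gca")
            if c in cohort_table.columns
        ]
        rmp_only = rmp_table[[c for c in rmp_table.columns if c == "patient_id" or c in RMP_COLUMNS]]
        bundle["correlations"] = st.spearman_matrix(rmp_only, cohort_table[clin_cols])

        if "mssi" in cohort_table.columns and "AAv" in rmp_table.columns:
            merged = rmp_table.merge(cohort_table[["patient_id", "mssi"]], on="patient_id")
            sub = merged[["AAv", "mssi"]].dropna()
            if len(sub) >= 4 and (sub["mssi"] >= 20).nunique() == 1:
                pass  # single severity class: ROC undefined
            elif len(sub) >= 4:
                roc = st.mssi_severity_roc(
                    -sub["AAv"], sub["mssi"],  # lower AAv marks worse disease
                    n_boot=config.bootstrap_replicates, seed=config.seed,
                )
                bundle["roc"] = pd.DataFrame([{
                    "score": "AAv", "auc": roc.auc, "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high, "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity, "threshold": roc.threshold,
                    "n": len(sub),
                }])

    if ctrl_rmp_table is not None and rmp_table is not None:
        rows = []
        for col in RMP_COLUMNS:
            if col not in rmp_table.columns or col not in ctrl_rmp_table.columns:
                continue
            a, b = rmp_table[col].dropna(), ctrl_rmp_table[col].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            cmp_ = st.compare_groups(a, b, col, config.percentile_method)
            rows.append({"parameter": col, "disease": cmp_.summary_a, "control": cmp_.summary_b,
                         "test": cmp_.test_used, "p_value": cmp_.p_value,
                         "n_disease": cmp_.n_a, "n_control": cmp_.n_b})
        bundle["comparisons"] = pd.DataFrame(rows)
    return bundle


def write_report_bundle(bundle: dict[str, pd.DataFrame], out_dir: str | Path, config: PipelineConfig) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        with open(out_dir / f"{name}.csv", "w") as fh:
            fh.write(_metadata_header(config))
            df.to_csv(fh, index=False)
    manifest = {"config": asdict(config), "config_hash": config.hash(), "outputs": sorted(bundle)}
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
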