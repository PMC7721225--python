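"""File dialects, run configuration, and pipeline orchestration.

All core I/O is plain delimited text (comma or tab, sniffed; UTF-8,
decimal point): the analysis consumes ROI-level thickness values, so no
neuroimaging container parsing is needed on the core path.

Dialects
--------
subject table
    header row; mandatory columns ``subject_id, group, arm``; covariate
    columns ``updrs_iii, pigd, disease_duration, gender, moca, nfogq``;
    speed columns ``speed_<timepoint>_<condition>`` in m/s for timepoints
    baseline/midpoint/final and conditions single/dual. Empty cells are
    missing values. Unknown columns are preserved as annotations.
thickness matrix
    first column ``subject_id``, remaining columns ``roi_<id>`` (mm).
parcellation table
    columns ``roi_id, network, vertex_count``; roi ids are 1-based.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .evaluation import screen_networks
from .gait import (
    CONDITIONS,
    GROUPS,
    TIMEPOINTS,
    SubjectRecord,
    filter_complete,
    required_timepoints,
    summarize_by_group,
)
from .parcellation import Parcellation, ThicknessMatrix, network_mean_thickness
from .stats import (
    ancova_group_effect,
    baseline_network_anova,
    independent_t,
    match_on_severity,
    mixed_anova,
)

__all__ = [
    "RunConfig",
    "read_subject_table",
    "write_subject_table",
    "read_thickness_matrix",
    "write_thickness_matrix",
    "read_parcellation",
    "write_parcellation",
    "run_pipeline",
]

logger = logging.getLogger("gaitpls")

_COVARIATE_COLUMNS = ("updrs_iii", "pigd", "disease_duration", "gender", "moca", "nfogq")
_SPEED_COLUMNS = tuple(
    f"speed_{tp}_{cond}" for tp in TIMEPOINTS for cond in CONDITIONS
)
_MANDATORY = ("subject_id", "group", "arm")

#: networks entering the baseline-thickness network x group ANOVA
BASELINE_ANOVA_NETWORKS = (
    "Default",
    "Dorsal attention",
    "Fronto-parietal",
    "Visual",
    "Somatosensory-lateral",
)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read the subject table into typed records (missing cells explicit)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise ValueError(f"subject table missing mandatory columns: {missing}")
    records = []
    for row_no, row in enumerate(frame.to_dict("records"), start=2):
        def _num(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                return None
            try:
                return float(v)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {v!r} in column {col!r}, row {row_no}"
                ) from None

        speeds = {}
        for tp in TIMEPOINTS:
            for cond in CONDITIONS:
                v = _num(f"speed_{tp}_{cond}")
                if v is not None:
                    speeds[(tp, cond)] = v
        gender = row.get("gender")
        if isinstance(gender, float) and math.isnan(gender):
            gender = None
        records.append(
            SubjectRecord(
                id=str(row["subject_id"]),
                group=str(row["group"]),
                arm=str(row["arm"]),
                speeds=speeds,
                updrs_iii=_num("updrs_iii"),
                pigd=_num("pigd"),
                disease_duration=_num("disease_duration"),
                gender=gender,
                moca=_num("moca"),
                nfogq=_num("nfogq"),
            )
        )
    return records


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.id, "group": r.group, "arm": r.arm}
        for c in _COVARIATE_COLUMNS:
            row[c] = getattr(r, c)
        for tp in TIMEPOINTS:
            for cond in CONDITIONS:
                row[f"speed_{tp}_{cond}"] = r.speeds.get((tp, cond))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_thickness_matrix(
    path: str | Path, parcellation: Parcellation | None = None
) -> ThicknessMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    if frame.columns[0] != "subject_id":
        raise ValueError("thickness matrix must start with a subject_id column")
    frame = frame.set_index("subject_id")
    matrix = ThicknessMatrix.from_frame(frame)
    if parcellation is not None:
        matrix.validate_against(parcellation)
    return matrix


def write_thickness_matrix(matrix: ThicknessMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def read_parcellation(path: str | Path) -> Parcellation:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    return Parcellation(frame)


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    parcellation.table.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    subject_path: str | Path | None = None
    thickness_path: str | Path | None = None
    parcellation_path: str | Path | None = None
    output_dir: str | Path | None = None
    cohorts: tuple[str, ...] = ("all", "freezers", "nonfreezers")
    matchings: tuple[str, ...] = ("unmatched", "matched")
    n_components: int = 4
    holdout: int = 3
    cap: int = 10_000
    n_null: int = 10_000
    alpha: float = 0.001
    es_threshold: float = 0.50
    seed: int | None = None
    scale_columns: bool = False
    weighted_network_means: bool = False
    boxcox_per_fold: bool = False
    welch: bool = False

    def validate(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.holdout < 1:
            raise ValueError("holdout must be >= 1")
        if self.cap < 1 or self.n_null < 1:
            raise ValueError("cap and n_null must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.cohorts) - {"all", "freezers", "nonfreezers"}
        if bad:
            raise ValueError(f"unknown cohorts: {sorted(bad)}")
        bad = set(self.matchings) - {"unmatched", "matched"}
        if bad:
            raise ValueError(f"unknown matchings: {sorted(bad)}")
        if self.seed is None:
            raise ValueError("seed is required (the null side is stochastic)")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for k in ("subject_path", "thickness_path", "parcellation_path", "output_dir"):
            d[k] = str(d[k]) if d[k] is not None else None
        d["cohorts"] = list(self.cohorts)
        d["matchings"] = list(self.matchings)
        return d


def _digest(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _stage(name: str, t0: float, seed_state: str = "") -> None:
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, seed_state)


def _select_cohort(records, thickness, cohort, matching, match_result):
    ids = set(thickness.subject_ids)
    if matching == "matched" and match_result is not None:
        ids &= set(match_result.kept)
    if cohort == "freezers":
        keep = [r for r in records if r.group == "freezer" and r.id in ids]
    elif cohort == "nonfreezers":
        keep = [r for r in records if r.group == "nonfreezer" and r.id in ids]
    else:
        keep = [r for r in records if r.id in ids]
    return keep


def _thickness_subset(thickness: ThicknessMatrix, ids: list[str]) -> ThicknessMatrix:
    pos = {s: i for i, s in enumerate(thickness.subject_ids)}
    rows = [pos[i] for i in ids]
    return ThicknessMatrix(ids, thickness.roi_ids, thickness.values[rows])


def run_pipeline(
    config: RunConfig,
    subjects: list[SubjectRecord] | None = None,
    thickness: ThicknessMatrix | None = None,
    parcellation: Parcellation | None = None,
) -> dict:
    """Run the full analysis and return a JSON-serializable report.

    Stages, in order: DTC and improvement computation -> cohort completeness
    filter -> group summary -> severity matching -> per-cohort Box-Cox +
    network screens -> group statistics. Inputs may be given as paths in
    ``config`` or as in-memory objects. The report is deterministic given
    (inputs, config, seed); it embeds the config echo, software version and
    input digests, and contains no timestamps.
    """
    config.validate()
    t0 = time.time()
    if subjects is None:
        if config.subject_path is None:
            raise ValueError("no subject table given")
        subjects = read_subject_table(config.subject_path)
    if parcellation is None:
        parcellation = (
            read_parcellation(config.parcellation_path)
            if config.parcellation_path
            else Parcellation.canonical()
        )
    if thickness is None:
        if config.thickness_path is None:
            raise ValueError("no thickness matrix given")
        thickness = read_thickness_matrix(config.thickness_path, parcellation)
    thickness.validate_against(parcellation)
    _stage("load", t0)

    report: dict = {
        "software_version": __version__,
        "config": config.to_dict(),
        "input_digests": {
            "subject_table": _digest(config.subject_path),
            "thickness_matrix": _digest(config.thickness_path),
            "parcellation": _digest(config.parcellation_path),
        },
        "thresholds": {
            # the screen's significance level, stated alongside the
            # conventional .05 used for the framing group statistics
            "screen_alpha": config.alpha,
            "group_stats_alpha": 0.05,
            "es_threshold": config.es_threshold,
        },
    }

    t = time.time()
    complete, excluded = filter_complete(subjects)
    report["cohort_filter"] = {
        "n_input": len(subjects),
        "n_complete": len(complete),
        "excluded_ids": sorted(r.id for r in excluded),
    }
    summary = summarize_by_group(complete)
    report["group_summary"] = summary.to_dict("records")
    _stage("summary", t)

    t = time.time()
    imaging = [r for r in complete if r.id in set(thickness.subject_ids)]
    by_group_n = {g: sum(1 for r in imaging if r.group == g) for g in GROUPS}
    match_result = None
    if min(by_group_n.values()) >= 2 and by_group_n["freezer"] != by_group_n["nonfreezer"]:
        match_result = match_on_severity(imaging, "updrs_iii")
        report["severity_matching"] = {
            "variable": "updrs_iii",
            "n_removed": match_result.n_removed,
            "removed_ids": match_result.removed_ids,
            "post_match_p": match_result.post_match_p,
        }
    else:
        report["severity_matching"] = None
    _stage("matching", t)

    t = time.time()
    screens: dict = {}
    rng_root = np.random.SeedSequence(config.seed)
    cells = [(c, m) for m in config.matchings for c in config.cohorts]
    children = rng_root.spawn(len(cells))
    for (cohort, matching), child in zip(cells, children):
        if matching == "matched" and match_result is None:
            continue
        members = _select_cohort(imaging, thickness, cohort, matching, match_result)
        key = f"{cohort}/{matching}"
        if len(members) < config.holdout + config.n_components + 1:
            screens[key] = {"error": f"too few subjects (n={len(members)})"}
            continue
        ids = [r.id for r in members]
        y = np.array([r.improvement for r in members], dtype=float)
        sub_thickness = _thickness_subset(thickness, ids)
        seed = int(child.generate_state(1)[0] % (2**31))
        reports = screen_networks(
            sub_thickness,
            parcellation,
            y,
            n_components=config.n_components,
            holdout=config.holdout,
            cap=config.cap,
            n_null=config.n_null,
            alpha=config.alpha,
            es_threshold=config.es_threshold,
            seed=seed,
            boxcox_per_fold=config.boxcox_per_fold,
        )
        screens[key] = {
            "n_subjects": len(members),
            "networks": [r.to_dict() for r in reports],
        }
    report["network_screens"] = screens
    _stage("screens", t)

    t = time.time()
    stats: dict = {}
    fr = [r for r in complete if r.group == "freezer"]
    nf = [r for r in complete if r.group == "nonfreezer"]
    if len(fr) >= 2 and len(nf) >= 2:
        tt = independent_t(
            [r.improvement for r in fr],
            [r.improvement for r in nf],
            welch=config.welch,
        )
        stats["improvement_t_test"] = {
            "t": tt.t, "df": tt.df, "p": tt.p, "mean_difference": tt.mean_difference,
            "variant": "welch" if config.welch else "pooled",
        }
        # group x time (pre/post of each subject's exercise period) on DTC
        pre_post = np.array(
            [[r.dtc(tp) for tp in required_timepoints(r.arm)] for r in complete],
            dtype=float,
        )
        groups = np.array([r.group for r in complete])
        stats["dtc_mixed_anova"] = (
            mixed_anova(pre_post, groups).reset_index(names="effect").to_dict("records")
        )
        covs = {
            "dtc_baseline": [r.dtc("baseline") for r in complete],
            "updrs_iii": [r.updrs_iii for r in complete],
            "pigd": [r.pigd for r in complete],
            "disease_duration": [r.disease_duration for r in complete],
            "gender": [1.0 if r.gender == "M" else 0.0 for r in complete],
        }
        improvement = [r.improvement for r in complete]
        ancovas = {}
        for name, cov in covs.items():
            if any(v is None for v in cov):
                ancovas[name] = {"error": "covariate missing for some subjects"}
                continue
            try:
                ancovas[name] = ancova_group_effect(improvement, groups, cov)
            except ValueError as exc:
                ancovas[name] = {"error": str(exc)}
        stats["ancova_per_covariate"] = ancovas
    for matching in config.matchings:
        if matching == "matched" and match_result is None:
            continue
        members = _select_cohort(imaging, thickness, "all", matching, match_result)
        gr = np.array([r.group for r in members])
        if len(set(gr)) < 2:
            continue
        sub = _thickness_subset(thickness, [r.id for r in members])
        net_means = network_mean_thickness(
            sub, parcellation, weighted=config.weighted_network_means
        )[list(BASELINE_ANOVA_NETWORKS)]
        stats[f"baseline_network_anova/{matching}"] = (
            baseline_network_anova(net_means, gr)
            .reset_index(names="effect")
            .to_dict("records")
        )
    report["group_stats"] = stats
    _stage("stats", t)

    report = _round_floats(report)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        _write_table3(report, out / "network_screens.tsv")
    _stage("total", t0)
    return report


def _write_table3(report: dict, path: Path) -> None:
    """Flat delimited view of the per-cohort network screen results."""
    rows = []
    for key, block in report.get("network_screens", {}).items():
        if "networks" not in block:
            continue
        cohort, matching = key.split("/")
        for r in block["networks"]:
            rows.append(
                {
                    "cohort": cohort,
                    "matching": matching,
                    "n_subjects": block["n_subjects"],
                    "network": r["network"],
                    "ES": r["effect_size"],
                    "R2": r["oos_r2"],
                    "p_value": r["p_value"],
                    "p_empirical": r["p_empirical"],
                    "first_score_R2": r["first_score_r2"],
                    "passed_screen": r["passed_screen"],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
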