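"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a cross-over exercise trial in Parkinson's disease
with two strata — freezers and nonfreezers (freezing of gait present or
absent) — whose dual-task-cost (DTC), improvement, and motor-severity
(MDS-UPDRS-III) marginals default to the study-scale anchors: baseline DTC
-18.0 +/- 10.1 % (freezers) and -13.9 +/- 9.8 % (nonfreezers), improvement
9.8 +/- 12.6 % versus 4.3 +/- 7.3 %, and MDS-UPDRS-III 46.0 +/- 12.7
versus 38.3 +/- 10.2. Cortical thickness is generated per ROI of a
parcellation as grand mean + network offset + ROI offset + subject effect
+ measurement noise (all in mm), and an optional linear brain-behavior
association is planted: the improvement of each subject depends on their
mean thickness over one chosen network with controllable strength ``beta``
(percent improvement per mm) and noise. Gait speeds at the three
timepoints are back-solved so that the DTC and improvement operations
reproduce the drawn values exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .gait import SubjectRecord
from .parcellation import Parcellation, ThicknessMatrix

__all__ = [
    "CohortSpec",
    "GeneratedCohort",
    "generate_thickness",
    "generate_outcome",
    "generate_cohort",
    "planted_network_variance",
    "planted_beta_for_r2",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; defaults are the study-scale conditions."""

    n_freezers: int = 21
    n_nonfreezers: int = 30
    # baseline dual-task cost on gait speed, percent, per stratum
    dtc_mean_freezers: float = -18.0
    dtc_sd_freezers: float = 10.1
    dtc_mean_nonfreezers: float = -13.9
    dtc_sd_nonfreezers: float = 9.8
    # exercise-induced improvement, percent, per stratum
    improvement_mean_freezers: float = 9.8
    improvement_sd_freezers: float = 12.6
    improvement_mean_nonfreezers: float = 4.3
    improvement_sd_nonfreezers: float = 7.3
    # MDS-UPDRS-III motor severity, score, per stratum
    updrs_mean_freezers: float = 46.0
    updrs_sd_freezers: float = 12.7
    updrs_mean_nonfreezers: float = 38.3
    updrs_sd_nonfreezers: float = 10.2
    # thickness variance components, mm
    thickness_grand_mean: float = 2.5
    network_offset_sd: float = 0.10
    roi_offset_sd: float = 0.10
    subject_effect_sd: float = 0.10
    measurement_noise_sd: float = 0.05
    # planted brain-behavior association
    planted_network: str | None = None
    beta: float = 0.0  # percent improvement per mm of planted-network mean
    outcome_noise_sd: float | None = None  # None -> per-stratum improvement SD
    seed: int = 0

    def validate(self, parcellation: Parcellation | None = None) -> None:
        sds = {
            "dtc_sd_freezers": self.dtc_sd_freezers,
            "dtc_sd_nonfreezers": self.dtc_sd_nonfreezers,
            "improvement_sd_freezers": self.improvement_sd_freezers,
            "improvement_sd_nonfreezers": self.improvement_sd_nonfreezers,
            "updrs_sd_freezers": self.updrs_sd_freezers,
            "updrs_sd_nonfreezers": self.updrs_sd_nonfreezers,
            "network_offset_sd": self.network_offset_sd,
            "roi_offset_sd": self.roi_offset_sd,
            "subject_effect_sd": self.subject_effect_sd,
            "measurement_noise_sd": self.measurement_noise_sd,
        }
        for name, sd in sds.items():
            if sd < 0:
                raise ValueError(f"{name} must be >= 0, got {sd}")
        if self.outcome_noise_sd is not None and self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be >= 0")
        for name, n in (
            ("n_freezers", self.n_freezers),
            ("n_nonfreezers", self.n_nonfreezers),
        ):
            if n != 0 and n < 4:
                raise ValueError(f"{name} must be 0 or >= 4 (leave-3-out needs >= 4)")
        if self.n_freezers + self.n_nonfreezers < 4:
            raise ValueError("total cohort size must be >= 4")
        total_sd = float(
            np.sqrt(
                self.network_offset_sd**2
                + self.roi_offset_sd**2
                + self.subject_effect_sd**2
                + self.measurement_noise_sd**2
            )
        )
        if self.thickness_grand_mean <= 3 * total_sd:
            raise ValueError(
                f"thickness grand mean {self.thickness_grand_mean} mm must exceed "
                f"3x the total thickness SD ({total_sd:.3f} mm) to assure positivity"
            )
        if parcellation is not None and self.planted_network is not None:
            if self.planted_network not in parcellation.networks:
                raise ValueError(
                    f"planted_network {self.planted_network!r} not in parcellation "
                    f"networks {parcellation.networks}"
                )

    def subject_ids(self) -> list[str]:
        return [f"F{i + 1:03d}" for i in range(self.n_freezers)] + [
            f"N{i + 1:03d}" for i in range(self.n_nonfreezers)
        ]

    def groups(self) -> list[str]:
        return ["freezer"] * self.n_freezers + ["nonfreezer"] * self.n_nonfreezers


@dataclass
class GeneratedCohort:
    """A generated cohort plus the ground truth that was planted into it."""

    subjects: list[SubjectRecord]
    thickness: ThicknessMatrix
    truth: dict = field(repr=False)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the three standard input files plus a truth sidecar (JSON)."""
        from . import io as _io

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "subjects": directory / "subjects.csv",
            "thickness": directory / "thickness.csv",
            "truth": directory / "truth.json",
        }
        _io.write_subject_table(self.subjects, paths["subjects"])
        _io.write_thickness_matrix(self.thickness, paths["thickness"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def planted_network_variance(spec: CohortSpec, parcellation: Parcellation) -> float:
    """Between-subject variance of the planted network's mean thickness.

    Network and ROI offsets are drawn once per cohort and therefore do not
    vary between subjects; only the subject effect and the ROI-averaged
    measurement noise do: ``var(x) = subject_effect_sd^2 + noise_sd^2 / m``
    with m the planted network's ROI count.
    """
    if spec.planted_network is None:
        raise ValueError("spec has no planted network")
    m = parcellation.size(spec.planted_network)
    return spec.subject_effect_sd**2 + spec.measurement_noise_sd**2 / m


def planted_beta_for_r2(
    spec: CohortSpec,
    parcellation: Parcellation,
    target_r2: float,
    noise_sd: float | None = None,
) -> float:
    """Association strength giving population R^2 = ``target_r2`` in one stratum.

    From R^2 = beta^2 var(x) / (beta^2 var(x) + sigma^2):
    ``beta = sigma * sqrt(R^2 / (1 - R^2)) / sd(x)``. ``noise_sd`` defaults
    to the freezer-stratum improvement SD (the residual outcome noise when
    ``outcome_noise_sd`` is unset).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    if noise_sd is None:
        noise_sd = (
            spec.outcome_noise_sd
            if spec.outcome_noise_sd is not None
            else spec.improvement_sd_freezers
        )
    var_x = planted_network_variance(spec, parcellation)
    return float(noise_sd * np.sqrt(target_r2 / (1 - target_r2)) / np.sqrt(var_x))


def generate_thickness(
    spec: CohortSpec, parcellation: Parcellation
) -> ThicknessMatrix:
    """Subjects x ROIs thickness (mm): grand mean + network offset + ROI
    offset + subject effect + measurement noise, all entries > 0.

    Network and ROI offsets are drawn once per cohort (shared across
    subjects); the subject effect is one draw per subject (shared across
    ROIs); the noise is independent per cell. Nonpositive cells are
    resampled (essentially never triggered given the positivity margin
    enforced by :meth:`CohortSpec.validate`).
    """
    spec.validate(parcellation)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = spec.n_freezers + spec.n_nonfreezers
    roi_ids = parcellation.roi_ids
    p = len(roi_ids)

    network_of_roi = parcellation.table.set_index("roi_id").loc[roi_ids, "network"]
    networks = parcellation.networks
    net_offset = dict(
        zip(networks, rng.normal(0.0, spec.network_offset_sd, size=len(networks)))
    )
    roi_offset = rng.normal(0.0, spec.roi_offset_sd, size=p)
    subject_effect = rng.normal(0.0, spec.subject_effect_sd, size=n)
    noise = rng.normal(0.0, spec.measurement_noise_sd, size=(n, p))

    base = (
        spec.thickness_grand_mean
        + np.array([net_offset[nm] for nm in network_of_roi])
        + roi_offset
    )
    values = base[None, :] + subject_effect[:, None] + noise
    for _ in range(100):
        bad = values <= 0
        if not bad.any():
            break
        values[bad] = (
            base[None, :] + subject_effect[:, None] + rng.normal(
                0.0, spec.measurement_noise_sd, size=values.shape
            )
        )[bad]
    else:
        raise RuntimeError("could not generate strictly positive thickness")
    return ThicknessMatrix(spec.subject_ids(), roi_ids, values)


# fixed within-stratum covariate anchors (mean, sd) on the study scale
_COVARIATE_ANCHORS = {
    "freezer": {
        "pigd": (6.2, 2.9),
        "disease_duration": (8.6, 5.5),
        "moca": (25.6, 3.8),
        "nfogq": (13.8, 5.5),
        "men_fraction": 30 / 39,
    },
    "nonfreezer": {
        "pigd": (4.4, 2.3),
        "disease_duration": (4.4, 3.7),
        "moca": (25.8, 3.2),
        "nfogq": None,
        "men_fraction": 24 / 43,
    },
}


def _truncated_normal(rng, mean, sd, low, high=np.inf):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if low < v < high:
            return float(v)
    return float(np.clip(mean, low + 1e-9, high))


def generate_outcome(
    spec: CohortSpec,
    thickness: ThicknessMatrix,
    parcellation: Parcellation,
) -> tuple[list[SubjectRecord], dict]:
    """Draw improvements (with the planted association) and back-solve speeds.

    The improvement of subject i is
    ``y_i = stratum_mean + beta * (x_i - grand_mean) + eps_i`` on the raw
    percent scale, where x_i is the subject's mean thickness over the
    planted network's ROIs (zero contribution when nothing is planted) and
    eps is Normal(0, outcome_noise_sd) with the per-stratum improvement SD
    as the default noise scale. Single-task speed is fixed at 1.0 m/s at
    all timepoints; dual-task speeds are back-solved from the drawn DTC
    trajectory so the DTC and improvement operations reproduce the drawn
    values exactly. Arms alternate within stratum.
    """
    spec.validate(parcellation)
    if thickness.subject_ids != spec.subject_ids():
        raise ValueError("thickness was not generated for this spec's subjects")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))

    if spec.planted_network is not None:
        from .parcellation import network_block

        x = network_block(thickness, parcellation, spec.planted_network).mean(axis=1)
        x_centered = x - spec.thickness_grand_mean
    else:
        x_centered = np.zeros(thickness.n_subjects)

    stratum_params = {
        "freezer": (
            spec.dtc_mean_freezers,
            spec.dtc_sd_freezers,
            spec.improvement_mean_freezers,
            spec.improvement_sd_freezers,
            spec.updrs_mean_freezers,
            spec.updrs_sd_freezers,
        ),
        "nonfreezer": (
            spec.dtc_mean_nonfreezers,
            spec.dtc_sd_nonfreezers,
            spec.improvement_mean_nonfreezers,
            spec.improvement_sd_nonfreezers,
            spec.updrs_mean_nonfreezers,
            spec.updrs_sd_nonfreezers,
        ),
    }

    subjects: list[SubjectRecord] = []
    latent: list[float] = []
    arm_counter = {"freezer": 0, "nonfreezer": 0}
    for i, (sid, group) in enumerate(zip(spec.subject_ids(), spec.groups())):
        dtc_m, dtc_sd, imp_m, imp_sd, upd_m, upd_sd = stratum_params[group]
        noise_sd = (
            spec.outcome_noise_sd if spec.outcome_noise_sd is not None else imp_sd
        )
        arm = ("exercise_first", "exercise_second")[arm_counter[group] % 2]
        arm_counter[group] += 1
        for _ in range(1000):
            improvement = (
                imp_m + spec.beta * x_centered[i] + rng.normal(0.0, noise_sd)
            )
            dtc_base = _truncated_normal(rng, dtc_m, dtc_sd, -95.0, 95.0)
            if arm == "exercise_first":
                dtc = {
                    "baseline": dtc_base,
                    "midpoint": dtc_base + improvement,
                }
                dtc["final"] = dtc["midpoint"]
            else:
                dtc = {"baseline": dtc_base, "midpoint": dtc_base}
                dtc["final"] = dtc["midpoint"] + improvement
            if all(-99.0 < v < 99.0 for v in dtc.values()):
                break
        else:
            raise RuntimeError("could not draw a feasible DTC trajectory")
        speeds = {}
        for tp, d in dtc.items():
            speeds[(tp, "single")] = 1.0
            speeds[(tp, "dual")] = 1.0 * (1.0 + d / 100.0)
        anchors = _COVARIATE_ANCHORS[group]
        nfogq = (
            _truncated_normal(rng, *anchors["nfogq"], low=0.5)
            if anchors["nfogq"] is not None
            else None
        )
        subjects.append(
            SubjectRecord(
                id=sid,
                group=group,
                arm=arm,
                speeds=speeds,
                updrs_iii=_truncated_normal(rng, upd_m, upd_sd, 0.0),
                pigd=_truncated_normal(rng, *anchors["pigd"], low=0.0),
                disease_duration=_truncated_normal(
                    rng, *anchors["disease_duration"], low=0.25
                ),
                gender="M" if rng.random() < anchors["men_fraction"] else "F",
                moca=_truncated_normal(rng, *anchors["moca"], low=0.0, high=30.0),
                nfogq=nfogq,
            )
        )
        latent.append(float(improvement))
    truth = {
        "planted_network": spec.planted_network,
        "beta": spec.beta,
        "seed": spec.seed,
        "latent_improvement": dict(zip(spec.subject_ids(), latent)),
        "spec": asdict(spec),
    }
    return subjects, truth


def generate_cohort(
    spec: CohortSpec, parcellation: Parcellation | None = None
) -> GeneratedCohort:
    """Generate a full cohort (thickness + subjects + truth) from a spec."""
    if parcellation is None:
        parcellation = Parcellation.canonical()
    thickness = generate_thickness(spec, parcellation)
    subjects, truth = generate_outcome(spec, thickness, parcellation)
    return GeneratedCohort(subjects, thickness, truth)
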