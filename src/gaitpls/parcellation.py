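"""ROI/network data model and thickness aggregation.

Cortical thickness arrives as one mean value (mm) per region of interest
(ROI) of a 333-ROI functional atlas whose ROIs group into 13 functional
networks (12 named systems plus an "Unassigned" category of 47 ROIs).
This module houses the :class:`Parcellation` (ROI -> network assignment
with vertex counts), the :class:`ThicknessMatrix` (subjects x ROIs, mm),
vertex-to-ROI averaging, and the extraction of per-network predictor
blocks and per-network mean thicknesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_NETWORK_SIZES",
    "UNASSIGNED",
    "GRAYORDINATES_PER_HEMISPHERE",
    "N_GRAYORDINATES",
    "Parcellation",
    "ThicknessMatrix",
    "vertex_to_roi",
    "network_block",
    "network_mean_thickness",
]

#: Network sizes of the canonical 333-ROI functional atlas grouping.
CANONICAL_NETWORK_SIZES: dict[str, int] = {
    "Auditory": 24,
    "Cingulo-opercular": 40,
    "Cingulo-parietal": 5,
    "Default": 41,
    "Dorsal attention": 32,
    "Fronto-parietal": 24,
    "Retrosplenial temporal": 8,
    "Somatosensory-lateral": 38,
    "Somatosensory-medial": 8,
    "Salience": 4,
    "Ventral attention": 23,
    "Visual": 39,
    "Unassigned": 47,
}

UNASSIGNED = "Unassigned"

#: Standard cortical-surface ("grayordinate") space: vertices per hemisphere.
GRAYORDINATES_PER_HEMISPHERE = 32_492
N_GRAYORDINATES = 2 * GRAYORDINATES_PER_HEMISPHERE  # 64,984

_FIXTURE_SEED = 333  # fixed seed for the synthetic canonical fixture


@dataclass(frozen=True)
class Parcellation:
    """ROI -> functional-network assignment with per-ROI vertex counts.

    ROI ids are 1-based, following atlas convention.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"roi_id", "network", "vertex_count"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        tab = self.table.copy()
        tab["roi_id"] = tab["roi_id"].astype(int)
        tab["vertex_count"] = tab["vertex_count"].astype(int)
        if tab["roi_id"].duplicated().any():
            dups = tab.loc[tab["roi_id"].duplicated(), "roi_id"].tolist()
            raise ValueError(f"duplicate roi_ids: {dups}")
        if (tab["vertex_count"] < 1).any():
            bad = tab.loc[tab["vertex_count"] < 1, "roi_id"].tolist()
            raise ValueError(f"vertex_count < 1 for roi_ids: {bad}")
        tab = tab.sort_values("roi_id").reset_index(drop=True)
        object.__setattr__(self, "table", tab)

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    @property
    def networks(self) -> list[str]:
        """Network names, canonical names first (in canonical order)."""
        present = set(self.table["network"])
        ordered = [n for n in CANONICAL_NETWORK_SIZES if n in present]
        extra = sorted(present - set(ordered))
        return ordered + extra

    def rois_in(self, network: str) -> np.ndarray:
        """ROI ids of ``network`` in ascending order."""
        if network not in set(self.table["network"]):
            raise KeyError(
                f"unknown network {network!r}; valid names: {self.networks}"
            )
        sub = self.table.loc[self.table["network"] == network, "roi_id"]
        return np.sort(sub.to_numpy())

    def size(self, network: str) -> int:
        return len(self.rois_in(network))

    @property
    def network_sizes(self) -> dict[str, int]:
        return {n: self.size(n) for n in self.networks}

    def vertex_counts(self, network: str) -> np.ndarray:
        """Vertex counts aligned to ``rois_in(network)``."""
        rois = self.rois_in(network)
        tab = self.table.set_index("roi_id")
        return tab.loc[rois, "vertex_count"].to_numpy()

    @classmethod
    def canonical(cls) -> "Parcellation":
        """The packaged 333-ROI fixture with the canonical network sizes.

        The ROI-id-to-network assignment and the per-ROI vertex counts are
        *synthetic* (generated from a fixed seed): only the network sizes —
        12 named systems plus 47 unassigned ROIs, summing to 333 — match the
        published atlas grouping. The real atlas tables are not shipped.
        """
        rng = np.random.default_rng(_FIXTURE_SEED)
        ids = rng.permutation(np.arange(1, 334))
        rows = []
        start = 0
        for network, size in CANONICAL_NETWORK_SIZES.items():
            for rid in ids[start : start + size]:
                rows.append((int(rid), network))
            start += size
        # partition the full grayordinate space across the 333 ROIs
        counts = rng.multinomial(N_GRAYORDINATES, np.full(333, 1.0 / 333))
        tab = pd.DataFrame(rows, columns=["roi_id", "network"]).sort_values("roi_id")
        tab["vertex_count"] = counts
        return cls(tab.reset_index(drop=True))


@dataclass(frozen=True)
class ThicknessMatrix:
    """Subjects x ROIs matrix of mean cortical thickness (mm)."""

    subject_ids: list[str]
    roi_ids: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        roi_ids = np.asarray(self.roi_ids, dtype=int)
        subject_ids = [str(s) for s in self.subject_ids]
        if values.shape != (len(subject_ids), len(roi_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(subject_ids)} subjects x {len(roi_ids)} ROIs"
            )
        if len(set(subject_ids)) != len(subject_ids):
            raise ValueError("duplicate subject ids")
        if len(np.unique(roi_ids)) != len(roi_ids):
            raise ValueError("duplicate roi ids")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite thickness at subject {subject_ids[i]!r}, roi {roi_ids[j]}"
            )
        if np.any(values <= 0):
            i, j = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"nonpositive thickness at subject {subject_ids[i]!r}, roi {roi_ids[j]}"
            )
        # store in ascending roi_id order so downstream indexing is canonical
        order = np.argsort(roi_ids)
        object.__setattr__(self, "roi_ids", roi_ids[order])
        object.__setattr__(self, "values", values[:, order])
        object.__setattr__(self, "subject_ids", subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=[f"roi_{r}" for r in self.roi_ids],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ThicknessMatrix":
        roi_ids = np.array([int(str(c).removeprefix("roi_")) for c in frame.columns])
        return cls(list(frame.index.astype(str)), roi_ids, frame.to_numpy(dtype=float))

    def validate_against(self, parcellation: Parcellation) -> None:
        mine, theirs = set(self.roi_ids.tolist()), set(parcellation.roi_ids.tolist())
        if mine != theirs:
            diff = sorted(mine.symmetric_difference(theirs))
            raise ValueError(f"ROI mismatch with parcellation; symmetric difference: {diff}")


def vertex_to_roi(
    vertex_thickness: np.ndarray,
    vertex_assignment: np.ndarray,
    roi_ids: np.ndarray | None = None,
) -> pd.Series:
    """Average per-vertex thickness (mm) into per-ROI values.

    Parameters
    ----------
    vertex_thickness : 1-d array of per-vertex thickness (mm).
    vertex_assignment : 1-d integer array, same length, mapping vertex -> roi id.
    roi_ids : optional explicit ROI set; any ROI with zero assigned vertices
        raises an error listing it.

    Returns
    -------
    Series indexed by roi id (ascending) of unweighted vertex means.
    """
    vertex_thickness = np.asarray(vertex_thickness, dtype=float)
    vertex_assignment = np.asarray(vertex_assignment)
    if vertex_thickness.shape != vertex_assignment.shape:
        raise ValueError("vertex_thickness and vertex_assignment lengths differ")
    means = (
        pd.Series(vertex_thickness)
        .groupby(pd.Series(vertex_assignment))
        .mean()
        .sort_index()
    )
    means.index.name = "roi_id"
    if roi_ids is not None:
        missing = sorted(set(np.asarray(roi_ids).tolist()) - set(means.index.tolist()))
        if missing:
            raise ValueError(f"ROIs with zero assigned vertices: {missing}")
        means = means.loc[np.sort(np.asarray(roi_ids))]
    return means


def network_block(
    thickness: ThicknessMatrix, parcellation: Parcellation, network: str
) -> np.ndarray:
    """Subjects x (ROIs in ``network``) predictor block, columns by ascending roi id."""
    thickness.validate_against(parcellation)
    rois = parcellation.rois_in(network)
    cols = np.searchsorted(thickness.roi_ids, rois)
    return thickness.values[:, cols]


def network_mean_thickness(
    thickness: ThicknessMatrix,
    parcellation: Parcellation,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-subject mean thickness (mm) of each network.

    The default is the unweighted mean over the network's ROI values; with
    ``weighted=True`` ROIs are weighted by their vertex counts (equivalent to
    the vertex-level mean).
    """
    out = {}
    for network in parcellation.networks:
        block = network_block(thickness, parcellation, network)
        if weighted:
            w = parcellation.vertex_counts(network).astype(float)
            out[network] = block @ (w / w.sum())
        else:
            out[network] = block.mean(axis=1)
    return pd.DataFrame(out, index=pd.Index(thickness.subject_ids, name="subject_id"))
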