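"""Core in-memory containers for a biallelic marker panel.

Genotypes are inbred/haploid-coded: one allele per call, stored as int8 with
0 and 1 for the two alleles and ``MISSING`` (−1) as the internal sentinel.
On disk the missing token is ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: chromosome universe for a tetraploid wheat map (A and B genomes)
WHEAT_CHROMOSOMES: tuple[str, ...] = tuple(
    f"{i}{g}" for i in range(1, 8) for g in ("A", "B")
)

MARKER_TYPES = ("PAV", "SNP")


def _check_unique(ids: np.ndarray, what: str) -> None:
    ids = np.asarray(ids)
    if len(ids) != len(set(ids.tolist())):
        vals, counts = np.unique(ids, return_counts=True)
        dup = vals[counts > 1][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class GenotypeMatrix:
    """Biallelic calls for markers × samples.

    Parameters
    ----------
    marker_ids, sample_ids : array-like of str
        Unique identifiers; rows are markers, columns are samples.
    calls : ndarray of int8, shape (n_markers, n_samples)
        Entries in {0, 1, MISSING}.
    marker_type : array-like of str
        Per-marker flag, ``"PAV"`` or ``"SNP"``.
    allele_labels : list of (str, str), optional
        Per-marker labels for the alleles coded 0 and 1. Defaults to
        ``("0", "1")`` for every marker.
    """

    marker_ids: np.ndarray
    sample_ids: np.ndarray
    calls: np.ndarray
    marker_type: np.ndarray
    allele_labels: list[tuple[str, str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.marker_type = np.asarray(self.marker_type, dtype=object)
        if self.calls.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers × {len(self.sample_ids)} samples"
            )
        _check_unique(self.marker_ids, "marker")
        _check_unique(self.sample_ids, "sample")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at marker "
                f"{self.marker_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        unknown = ~np.isin(self.marker_type, MARKER_TYPES)
        if unknown.any():
            raise ValueError(
                f"unknown marker type {self.marker_type[unknown][0]!r}"
            )
        if self.allele_labels is None:
            self.allele_labels = [("0", "1")] * self.n_markers
        if len(self.allele_labels) != self.n_markers:
            raise ValueError("allele_labels length does not match marker count")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def marker_index(self) -> dict:
        return {m: i for i, m in enumerate(self.marker_ids)}

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset by boolean mask or integer/label index over markers."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            lookup = self.marker_index()
            idx = np.array([lookup[m] for m in keep], dtype=int)
        return GenotypeMatrix(
            self.marker_ids[idx],
            self.sample_ids,
            self.calls[idx],
            self.marker_type[idx],
            [self.allele_labels[i] for i in idx],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([lookup[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            self.marker_ids,
            self.sample_ids[idx],
            self.calls[:, idx],
            self.marker_type,
            self.allele_labels,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.marker_ids, other.marker_ids)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.marker_type, other.marker_type)
            and list(self.allele_labels) == list(other.allele_labels)
        )


@dataclass
class GeneticMap:
    """Marker → (chromosome, cM) assignments.

    ``chromosomes`` declares the name universe; defaults to the 14 wheat
    A/B-genome chromosomes.
    """

    table: pd.DataFrame  # columns: marker_id, chromosome, position_cM
    chromosomes: tuple[str, ...] = WHEAT_CHROMOSOMES

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker_id", "chromosome", "position_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        _check_unique(t["marker_id"].to_numpy(), "mapped marker")
        if (t["position_cM"] < 0).any():
            bad = t.loc[t["position_cM"] < 0, "marker_id"].iloc[0]
            raise ValueError(f"negative cM position for marker {bad!r}")
        unknown = set(t["chromosome"]) - set(self.chromosomes)
        if unknown:
            raise ValueError(f"chromosome(s) outside declared universe: {sorted(unknown)}")
        self.table = t.reset_index(drop=True)

    def mapped_mask(self, marker_ids: np.ndarray) -> np.ndarray:
        mapped = set(self.table["marker_id"])
        return np.array([m in mapped for m in marker_ids], dtype=bool)

    def positions(self, marker_ids) -> pd.DataFrame:
        """Chromosome/position rows aligned to ``marker_ids`` (inner order preserved)."""
        idx = self.table.set_index("marker_id")
        missing = [m for m in marker_ids if m not in idx.index]
        if missing:
            raise KeyError(f"unmapped marker(s): {missing[:5]}")
        return idx.loc[list(marker_ids)].reset_index()


@dataclass
class SampleMetadata:
    """Per-sample annotations: era (landrace/modern), origin, subpopulation,
    and optional numeric covariates (e.g. heading date in days)."""

    table: pd.DataFrame  # columns: sample_id, era, origin, subpopulation, + covariates

    ERAS = ("landrace", "modern")

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "sample_id" not in t.columns or "era" not in t.columns:
            raise ValueError("metadata needs at least sample_id and era columns")
        _check_unique(t["sample_id"].to_numpy(), "sample")
        bad_era = set(t["era"]) - set(self.ERAS)
        if bad_era:
            raise ValueError(f"unknown era label(s): {sorted(bad_era)}")
        if "subpopulation" in t.columns:
            labels = set(t["subpopulation"].dropna())
            allowed = {f"SP{i}" for i in range(1, 10)} | {"admixed"}
            bad = labels - allowed
            if bad:
                raise ValueError(f"unknown subpopulation label(s): {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy(dtype=object)

    def aligned_to(self, sample_ids: np.ndarray) -> "SampleMetadata":
        idx = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise ValueError(f"metadata missing for sample(s): {missing[:5]}")
        return SampleMetadata(idx.loc[list(sample_ids)].reset_index())

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"no covariate column {name!r}")
        return self.table[name].to_numpy(dtype=float)
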