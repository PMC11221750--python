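"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Marker tables are :class:`pandas.DataFrame` objects with columns
  ``chrom`` (str), ``pos`` (int, 1-based as in VCF), ``ref``, ``alt``.
  Positions are strictly increasing within a chromosome.
* Haplotype alleles are coded 0 (ref), 1 (alt); missing genotypes are
  coded :data:`MISSING` on *both* haplotypes of a sample.
* Ancestry codes: 0 = olive-like, 1 = yellow-like.
* Tract bp intervals are 0-based half-open (BED-like); marker indices
  are half-open ``[start, end)`` into the marker table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

ANCESTRY_NAMES = {0: "olive", 1: "yellow"}

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]


def make_markers(chrom, pos, ref=None, alt=None) -> pd.DataFrame:
    """Assemble and validate a marker table."""
    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object) if ref is not None else ["A"] * n,
            "alt": np.asarray(alt, dtype=object) if alt is not None else ["G"] * n,
        }
    )
    validate_markers(df)
    return df


def validate_markers(markers: pd.DataFrame) -> None:
    for col in MARKER_COLUMNS:
        if col not in markers.columns:
            raise ValueError(f"marker table missing column {col!r}")
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")


def chrom_slices(markers: pd.DataFrame) -> list[tuple[str, slice]]:
    """Contiguous marker-index slice per chromosome, in table order."""
    out = []
    chroms = markers["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append((chroms[start], slice(start, i)))
            start = i
    return out


@dataclass
class PopulationFrequencies:
    """Per-marker alternate-allele frequencies in two reference populations.

    ``freq`` has shape (n_markers, 2): column 0 is the olive-like
    population, column 1 the yellow-like one.  ``ancestral`` is the
    shared ancestral frequency each population diverged from.
    """

    markers: pd.DataFrame
    freq: np.ndarray
    ancestral: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.ancestral = np.asarray(self.ancestral, dtype=float)
        n = len(self.markers)
        if self.freq.shape != (n, 2):
            raise ValueError("freq must have shape (n_markers, 2)")
        if self.ancestral.shape != (n,):
            raise ValueError("ancestral must have shape (n_markers,)")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("frequencies outside [0, 1]")
        if np.any((self.ancestral < 0) | (self.ancestral > 1)):
            raise ValueError("ancestral frequencies outside [0, 1]")
        validate_markers(self.markers)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a cohort.

    ``haplotypes`` has shape (n_samples, 2, n_markers), int8, values in
    {0, 1} plus :data:`MISSING` once ``degraded`` is set.
    """

    markers: pd.DataFrame
    samples: list[str]
    haplotypes: np.ndarray
    phased: bool = True
    degraded: bool = False

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.samples), 2, len(self.markers)):
            raise ValueError("haplotypes must have shape (n_samples, 2, n_markers)")
        if not self.degraded and np.any(self.haplotypes == MISSING):
            raise ValueError("missing alleles present but degraded flag not set")
        validate_markers(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in panel") from None

    def dosages(self) -> np.ndarray:
        """Diploid alt-allele dosage (n_samples, n_markers); MISSING where masked."""
        h = self.haplotypes
        d = h[:, 0, :].astype(np.int16) + h[:, 1, :].astype(np.int16)
        d[np.any(h == MISSING, axis=1)] = MISSING
        return d

    def subset_markers(self, index) -> "HaplotypePanel":
        index = np.asarray(index)
        return replace(
            self,
            markers=self.markers.iloc[index].reset_index(drop=True),
            haplotypes=self.haplotypes[:, :, index],
        )

    def subset_samples(self, samples: list[str]) -> "HaplotypePanel":
        idx = [self.sample_index(s) for s in samples]
        return replace(self, samples=list(samples), haplotypes=self.haplotypes[idx])

    def copy(self) -> "HaplotypePanel":
        return replace(
            self,
            markers=self.markers.copy(),
            samples=list(self.samples),
            haplotypes=self.haplotypes.copy(),
        )


@dataclass
class TractSet:
    """Per-haplotype local-ancestry assignments on a marker grid.

    Stored densely as an int8 array (n_samples, 2, n_markers); runs of
    constant ancestry are materialised as tracts on demand.  The dense
    form guarantees the tiling invariant (tracts cover every marker,
    no overlap) by construction.
    """

    markers: pd.DataFrame
    samples: list[str]
    ancestry: np.ndarray
    codes: dict = field(default_factory=lambda: dict(ANCESTRY_NAMES))

    def __post_init__(self):
        self.ancestry = np.asarray(self.ancestry, dtype=np.int8)
        if self.ancestry.shape != (len(self.samples), 2, len(self.markers)):
            raise ValueError("ancestry must have shape (n_samples, 2, n_markers)")
        validate_markers(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in tract set") from None

    def subset_samples(self, samples: list[str]) -> "TractSet":
        idx = [self.sample_index(s) for s in samples]
        return TractSet(self.markers, list(samples), self.ancestry[idx], dict(self.codes))

    def copy(self) -> "TractSet":
        return TractSet(self.markers.copy(), list(self.samples), self.ancestry.copy(), dict(self.codes))

    def tracts(self) -> pd.DataFrame:
        """Tract table: sample, hap, chrom, start, end, start_idx, end_idx, ancestry.

        bp intervals are 0-based half-open; a tract starts at its first
        marker's 0-based position and ends at the next tract's start, the
        last tract on a chromosome extending to last marker position + 1
        (in 0-based coordinates: the 1-based position itself).
        """
        rows = []
        pos = self.markers["pos"].to_numpy()
        for chrom, sl in chrom_slices(self.markers):
            p = pos[sl]
            for si, sample in enumerate(self.samples):
                for hap in (0, 1):
                    anc = self.ancestry[si, hap, sl]
                    bounds = np.flatnonzero(np.diff(anc)) + 1
                    starts = np.concatenate([[0], bounds])
                    ends = np.concatenate([bounds, [len(anc)]])
                    for a, b in zip(starts, ends):
                        start_bp = int(p[a]) - 1
                        end_bp = int(p[b]) - 1 if b < len(anc) else int(p[-1])
                        rows.append(
                            (sample, hap, chrom, start_bp, end_bp,
                             int(sl.start + a), int(sl.start + b), int(anc[a]))
                        )
        return pd.DataFrame(
            rows,
            columns=["sample", "hap", "chrom", "start", "end",
                     "start_idx", "end_idx", "ancestry"],
        )


@dataclass
class Pedigree:
    """Individual/sire/dam records with taxon labels and generations.

    ``table`` columns: id, sire, dam, sex, taxon, generation.  Unknown
    parents are recorded as "0".  Taxon labels are "olive", "yellow" or
    "cross".
    """

    table: pd.DataFrame

    COLUMNS = ["id", "sire", "dam", "sex", "taxon", "generation"]

    def __post_init__(self):
        for col in self.COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"pedigree missing column {col!r}")
        self.validate()

    def validate(self) -> None:
        tab = self.table
        ids = set(tab["id"])
        if len(ids) != len(tab):
            raise ValueError("duplicate individual ids in pedigree")
        parents = {}
        for _, row in tab.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent != "0" and parent not in ids:
                    raise ValueError(f"parent {parent!r} of {row['id']!r} not in pedigree")
            parents[row["id"]] = [p for p in (row["sire"], row["dam"]) if p != "0"]
        # no individual may be its own ancestor
        for ind in parents:
            stack, seen = list(parents[ind]), set()
            while stack:
                a = stack.pop()
                if a == ind:
                    raise ValueError(f"{ind!r} is its own ancestor")
                if a not in seen:
                    seen.add(a)
                    stack.extend(parents[a])

    def founders(self) -> list[str]:
        tab = self.table
        mask = (tab["sire"] == "0") & (tab["dam"] == "0")
        return list(tab.loc[mask, "id"])

    def generation_of(self, sample: str) -> int:
        row = self.table.loc[self.table["id"] == sample]
        if row.empty:
            raise KeyError(sample)
        return int(row["generation"].iloc[0])


@dataclass
class HmmConfig:
    """Tunables of the two-state local-ancestry HMM.

    ``generations``: generations since admixture g (controls the
    switch-rate per Morgan); ``error_floor``: emission clamp ε keeping
    reference frequencies away from 0/1; ``prior``: stationary state
    prior (olive, yellow).
    """

    generations: float = 8.0
    error_floor: float = 0.005
    prior: tuple = (0.5, 0.5)

    def __post_init__(self):
        if not self.generations > 0:
            raise ValueError("generations must be > 0")
        if not 0 < self.error_floor < 0.5:
            raise ValueError("error_floor must be in (0, 0.5)")
        p = np.asarray(self.prior, dtype=float)
        if p.shape != (2,) or abs(p.sum() - 1) > 1e-9 or np.any(p <= 0):
            raise ValueError("prior must be two positive values summing to 1")
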