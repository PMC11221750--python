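"""Genetic-map construction, interpolation and file dialects.

A recombination-rate map (tab-separated chrom/start/end/rate, rate in
crossover probability per bp) is converted to cumulative genetic
distance with the standard equivalence 1 cM/Mb = 1e-8 per bp: the
genetic length of an interval is (end - start) * rate * 100 cM, and
cumulative cM is the running sum from the chromosome start.  Gaps
between rate intervals contribute 0 cM; positions outside the mapped
span clamp to the terminal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear map from bp to cumulative cM.

    ``nodes`` maps chromosome id to (positions_bp, cumulative_cm), both
    1-D float arrays with positions strictly increasing and cM
    non-decreasing, starting at 0 at the chromosome's first node.
    """

    nodes: dict = field(default_factory=dict)

    def __post_init__(self):
        for chrom, (bp, cm) in self.nodes.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.ndim != 1 or bp.shape != cm.shape or len(bp) == 0:
                raise ValueError(f"malformed nodes for chromosome {chrom}")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"node positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < -1e-12):
                raise ValueError(f"cumulative cM decreases on {chrom}")
            self.nodes[chrom] = (bp, cm)

    @property
    def chroms(self) -> list:
        return list(self.nodes)

    def interpolate(self, chrom, pos):
        """Cumulative cM at ``pos`` (scalar or array), clamped to map span."""
        if chrom not in self.nodes:
            raise KeyError(f"chromosome {chrom!r} not in map")
        bp, cm = self.nodes[chrom]
        return np.interp(pos, bp, cm)

    def length_cm(self, chrom) -> float:
        bp, cm = self.nodes[chrom]
        return float(cm[-1] - cm[0])

    def length_morgans(self, chrom) -> float:
        return self.length_cm(chrom) / 100.0

    def position_at_cm(self, chrom, cm_value):
        """Inverse interpolation: physical position at a cumulative cM value."""
        bp, cm = self.nodes[chrom]
        # np.interp requires increasing x; cM plateaus (rate-0 gaps) resolve
        # to the left edge, which is adequate for crossover placement.
        return np.interp(cm_value, cm, bp)


def cm_from_rate(intervals) -> GeneticMap:
    """Build a :class:`GeneticMap` from rate intervals.

    ``intervals``: DataFrame or records with columns/fields
    (chrom, start, end, rate), rate in per-bp recombination probability.
    Each interval contributes (end - start) * rate * 100 cM.
    """
    if not isinstance(intervals, pd.DataFrame):
        intervals = pd.DataFrame(intervals, columns=["chrom", "start", "end", "rate"])
    if np.any(intervals["rate"].to_numpy(dtype=float) < 0):
        raise ValueError("negative recombination rate")
    nodes = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        start = grp["start"].to_numpy(dtype=float)
        end = grp["end"].to_numpy(dtype=float)
        rate = grp["rate"].to_numpy(dtype=float)
        if np.any(end < start):
            raise ValueError(f"interval with end < start on {chrom}")
        order = np.argsort(start, kind="stable")
        start, end, rate = start[order], end[order], rate[order]
        if np.any(start[1:] < end[:-1]):
            raise ValueError(f"overlapping intervals on {chrom}")
        seg_cm = (end - start) * rate * 100.0
        bp_nodes = [start[0]]
        cm_nodes = [0.0]
        cum = 0.0
        for s, e, g in zip(start, end, seg_cm):
            if s > bp_nodes[-1]:
                bp_nodes.append(s)  # gap: flat segment, 0 cM
                cm_nodes.append(cum)
            cum += g
            if e > bp_nodes[-1]:
                bp_nodes.append(e)
                cm_nodes.append(cum)
        nodes[chrom] = (np.array(bp_nodes), np.array(cm_nodes))
    return GeneticMap(nodes)


def uniform_map(chrom_lengths: dict, rate: float = 1e-8) -> GeneticMap:
    """Constant-rate map covering [0, length] for each chromosome."""
    intervals = [(c, 0, length, rate) for c, length in chrom_lengths.items()]
    return cm_from_rate(pd.DataFrame(intervals, columns=["chrom", "start", "end", "rate"]))


def read_rate_map(path) -> GeneticMap:
    """Read a tab-separated chrom/start/end/rate file (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "rate"], dtype={"chrom": str})
    if isinstance(df["start"].iloc[0], str):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["rate"] = df["rate"].astype(float)
    return cm_from_rate(df)


def write_map(gmap: GeneticMap, markers: pd.DataFrame, path, dialect: str) -> None:
    """Write marker genetic positions in PLINK or SHAPEIT dialect.

    plink: 4 columns (chrom, marker id, cM, bp), no header.
    shapeit: 3 columns with header line "pos chr cM".
    """
    if dialect not in ("plink", "shapeit"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    if dialect == "shapeit":
        lines.append("pos\tchr\tcM")
    for _, row in markers.iterrows():
        cm = float(gmap.interpolate(row["chrom"], row["pos"]))
        if dialect == "plink":
            mid = f"{row['chrom']}:{row['pos']}"
            lines.append(f"{row['chrom']}\t{mid}\t{cm:.8g}\t{row['pos']}")
        else:
            lines.append(f"{row['pos']}\t{row['chrom']}\t{cm:.8g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_map(path, dialect: str) -> GeneticMap:
    """Read a PLINK- or SHAPEIT-dialect map back into a :class:`GeneticMap`."""
    if dialect == "plink":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "id", "cm", "pos"], dtype={"chrom": str})
    elif dialect == "shapeit":
        df = pd.read_csv(path, sep="\t", dtype={"chr": str})
        if list(df.columns) != ["pos", "chr", "cM"]:
            raise ValueError("malformed shapeit map header")
        df = df.rename(columns={"chr": "chrom", "cM": "cm"})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    nodes = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        bp = grp["pos"].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        order = np.argsort(bp, kind="stable")
        bp, cm = bp[order], cm[order]
        if np.any(np.diff(cm) < -1e-9):
            raise ValueError(f"non-monotone cM in map file on {chrom}")
        nodes[chrom] = (bp, cm)
    return GeneticMap(nodes)
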