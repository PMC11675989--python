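"""Flanking windows around associated markers and positional candidate genes.

Each suggestive/significant marker gets a +/- flank window (default 500 kb
each side); same-chromosome markers closer than the merge gap (default 1 Mb)
collapse into one window spanning min(pos) - flank to max(pos) + flank.
Genes overlapping a window are reported with the distance from the nearest
member SNP to the nearer gene edge (0 and relation "intron/inside" when the
SNP falls within the gene).  Upstream/downstream is positional (strandless):
a gene entirely below the SNP coordinate is upstream.

Coordinates are 1-based inclusive; BED input (0-based half-open) is converted
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class GeneWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    members: list[tuple[str, int]] = field(default_factory=list)  # (variant id, pos)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end <= self.start:
            raise ValueError(f"bad window [{self.start}, {self.end}]")
        self.members = sorted(self.members, key=lambda t: t[1])


@dataclass
class CandidateGene:
    window: GeneWindow
    gene: str
    gene_start: int
    gene_end: int
    nearest_snp: str
    distance: int  # bp from nearest member SNP to nearer gene edge; 0 if inside
    relation: str  # intron/inside | upstream | downstream


def build_windows(
    hits: pd.DataFrame,
    flank: int = 500_000,
    merge_gap: int = 1_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GeneWindow]:
    """Windows of +/- flank around hits (columns id/chrom/pos), merging
    same-chromosome hits within merge_gap of each other."""
    if len(hits) == 0:
        return []
    hits = hits.sort_values(["chrom", "pos"]).reset_index(drop=True)
    windows: list[GeneWindow] = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        cluster: list[tuple[str, int]] = []
        prev_pos = None
        for _, row in sub.iterrows():
            if prev_pos is not None and row["pos"] - prev_pos > merge_gap:
                windows.append(_make_window(str(chrom), cluster, flank, chrom_lengths))
                cluster = []
            cluster.append((str(row["id"]), int(row["pos"])))
            prev_pos = int(row["pos"])
        windows.append(_make_window(str(chrom), cluster, flank, chrom_lengths))
    return windows


def _make_window(
    chrom: str,
    members: list[tuple[str, int]],
    flank: int,
    chrom_lengths: dict[str, int] | None,
) -> GeneWindow:
    # width of a single-SNP window is exactly 2*flank (1-based inclusive)
    lo = min(p for _, p in members) - flank + 1
    hi = max(p for _, p in members) + flank
    lo = max(lo, 1)
    if chrom_lengths and chrom in chrom_lengths:
        hi = min(hi, chrom_lengths[chrom])
    return GeneWindow(chrom=chrom, start=lo, end=hi, members=members)


def read_gene_annotation(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Gene table (chrom/start/end/name, 1-based inclusive) from a 4-column
    TSV or a BED file (BED's 0-based half-open converted on read)."""
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "tsv"
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=range(4),
        dtype={"chrom": str},
    )
    if fmt == "bed":
        df["start"] = df["start"] + 1
    return df


def annotate_windows(
    windows: list[GeneWindow], genes: pd.DataFrame
) -> list[CandidateGene]:
    """Genes overlapping each window with the distance from the nearest
    member SNP (nearest-edge convention)."""
    out: list[CandidateGene] = []
    genes = genes.copy()
    genes["chrom"] = genes["chrom"].astype(str)
    for w in windows:
        sub = genes[
            (genes["chrom"] == w.chrom)
            & (genes["end"] >= w.start)
            & (genes["start"] <= w.end)
        ]
        for _, g in sub.iterrows():
            gs, ge = int(g["start"]), int(g["end"])
            best = None
            for vid, pos in w.members:
                if gs <= pos <= ge:
                    cand = (0, vid, "intron/inside")
                elif pos < gs:
                    cand = (gs - pos, vid, "downstream")  # gene lies above the SNP
                else:
                    cand = (pos - ge, vid, "upstream")    # gene lies below the SNP
                if best is None or cand[0] < best[0]:
                    best = cand
            dist, vid, rel = best
            out.append(
                CandidateGene(
                    window=w, gene=str(g["name"]), gene_start=gs, gene_end=ge,
                    nearest_snp=vid, distance=int(dist), relation=rel,
                )
            )
    return out


def candidate_table(candidates: list[CandidateGene]) -> pd.DataFrame:
    """Flat hit-list table (chrom, SNP, position, gene, distance kb, relation)."""
    rows = []
    for c in candidates:
        pos = dict(c.window.members)[c.nearest_snp]
        rows.append(
            {
                "chrom": c.window.chrom,
                "snp": c.nearest_snp,
                "pos": pos,
                "gene": c.gene,
                "distance_kb": round(c.distance / 1000.0, 1),
                "relation": c.relation,
            }
        )
    return pd.DataFrame(rows)
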