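"""ChIP-seq signal aggregation over promoter windows and gene bodies.

Tracks are bedGraph intervals carrying S = -log10 P per tag.  A gene's
signal <S> is the unweighted mean of S over all tags overlapping the region
(a tag "matches" if it overlaps the region at all).  Includes the
expression flooring rule, promoter window-size tuning against expression,
and reference hESC line selection by mutual similarity.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    BedFormatError,
    GeneAnnotation,
    GenomicInterval,
    gene_body_interval,
    promoter_window,
)

DEFAULT_WINDOW = 300
WINDOW_CANDIDATES = (200, 300, 500, 700, 900, 1100, 1300, 1500)


class SignalTrack:
    """Sorted, non-overlapping bedGraph intervals with S >= 0 per chromosome."""

    def __init__(self, chroms: Sequence[str], starts: Sequence[int], ends: Sequence[int], values: Sequence[float]):
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chroms, dtype=object),
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64),
                "value": np.asarray(values, dtype=float),
            }
        )
        if len(df) and (df["end"] <= df["start"]).any():
            bad = df.index[(df["end"] <= df["start"])][0]
            raise ValueError(f"empty interval at record {bad}")
        if len(df) and (df["value"] < 0).any():
            raise ValueError("negative S value in track (S = -log10 P must be >= 0)")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            overlap = grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                rows = grp.iloc[[i, i + 1]][["start", "end"]].to_numpy().tolist()
                raise ValueError(f"overlapping intervals on {chrom}: {rows}")
        self._df = df
        self._by_chrom = {
            chrom: (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["value"].to_numpy(),
            )
            for chrom, grp in df.groupby("chrom", sort=False)
        }

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def tags_overlapping(self, iv: GenomicInterval) -> np.ndarray:
        """S values of all tags overlapping ``iv`` (half-open)."""
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return np.empty(0)
        starts, ends, values = entry
        # non-overlapping sorted tags: overlap iff start < iv.end and end > iv.start
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        return values[lo:hi]


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a validated SignalTrack."""
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError("bedGraph needs 4 tab-separated fields", ln)
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedFormatError(str(exc), ln) from exc
            if v < 0:
                raise BedFormatError(f"negative S value {v}", ln)
            if s < 0 or e <= s:
                raise BedFormatError(f"invalid interval [{s}, {e})", ln)
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
            values.append(v)
    return SignalTrack(chroms, starts, ends, values)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    track.frame.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def mean_signal_over_interval(track: SignalTrack, iv: GenomicInterval) -> float:
    """Unweighted mean S over tags overlapping ``iv``; NaN when none match."""
    vals = track.tags_overlapping(iv)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def promoter_signal_matrix(
    track: SignalTrack, genes: Sequence[GeneAnnotation], w: int = DEFAULT_WINDOW
) -> pd.Series:
    """Per-gene <S> over the symmetric +/-w promoter window."""
    out = {}
    for g in genes:
        out[g.gene_id] = mean_signal_over_interval(track, promoter_window(g, w, "symmetric"))
    s = pd.Series(out, name="signal")
    n_missing = int(s.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} gene(s) with no overlapping promoter tag", stacklevel=2)
    return s


def gene_body_signal(
    track: SignalTrack, genes: Sequence[GeneAnnotation], mode: str = "with_introns"
) -> pd.Series:
    """Per-gene <S> over the gene body region(s) under the chosen definition."""
    out = {}
    for g in genes:
        regions = gene_body_interval(g, mode)
        if not regions:
            out[g.gene_id] = float("nan")
            continue
        vals = np.concatenate([track.tags_overlapping(iv) for iv in regions])
        out[g.gene_id] = float(vals.mean()) if vals.size else float("nan")
    return pd.Series(out, name="signal")


def floor_expression(
    rpkm: pd.Series,
    total_reads_millions: float = 39,
    read_threshold: float = 10,
    mean_gene_kb: float = 1,
) -> pd.Series:
    """log2 expression with zero substitution and a low-count floor.

    Zeros are replaced by the smallest positive RPKM observed, then log2 is
    taken and values below the floor are clamped to it.  The floor is the
    rounded log2 RPKM that ``read_threshold`` reads correspond to given the
    library size and mean gene length (10 reads / (39 M x 1 kb) -> -2).
    """
    x = rpkm.astype(float).copy()
    if (x < 0).any():
        raise ValueError("RPKM values must be >= 0")
    positive = x[x > 0]
    if positive.empty:
        raise ValueError("all-zero expression vector")
    x[x == 0] = positive.min()
    logx = np.log2(x)
    floor = round(np.log2(read_threshold / (total_reads_millions * mean_gene_kb)))
    return logx.clip(lower=floor)


def tune_window(
    track_k4: SignalTrack,
    track_k27: SignalTrack,
    expression: pd.Series,
    genes: Sequence[GeneAnnotation],
    candidates: Sequence[int] = WINDOW_CANDIDATES,
) -> tuple[int, pd.DataFrame]:
    """Choose the promoter window size maximising signal-expression coupling.

    For every candidate w the promoter <S> of both bivalent marks is
    correlated (Pearson) with expression over shared genes; the objective is
    the mean |r| of the two marks and ties go to the smallest w.  The full
    per-mark correlation profile is returned alongside the chosen w.
    """
    if len(candidates) < 2:
        raise ValueError("need >=2 candidate window sizes")
    rows = []
    for w in sorted(candidates):
        s4 = promoter_signal_matrix(track_k4, genes, w)
        s27 = promoter_signal_matrix(track_k27, genes, w)
        common4 = expression.index.intersection(s4.dropna().index)
        common27 = expression.index.intersection(s27.dropna().index)
        if min(len(common4), len(common27)) < 50:
            raise ValueError("fewer than 50 genes shared between signals and expression")
        r4 = float(np.corrcoef(s4[common4], expression[common4])[0, 1])
        r27 = float(np.corrcoef(s27[common27], expression[common27])[0, 1])
        rows.append({"window": w, "r_k4": r4, "r_k27": r27,
                     "objective": (abs(r4) + abs(r27)) / 2})
    profile = pd.DataFrame(rows)
    best = profile.sort_values(["objective", "window"], ascending=[False, True], kind="stable")
    return int(best.iloc[0]["window"]), profile


def select_reference_line(line_signals: Mapping[str, pd.DataFrame]) -> tuple[str, pd.DataFrame]:
    """Pick the cell line most similar to the others.

    ``line_signals`` maps line id -> gene x mark signal frame (same columns
    across lines).  Similarity of a pair of lines is the mean Pearson
    correlation over the shared marks; a line's score is the mean similarity
    to every other line.  Returns the argmax line (ties lexicographic) and
    the full pairwise similarity matrix.
    """
    lines = sorted(line_signals)
    if len(lines) < 3:
        raise ValueError("need >=3 cell lines")
    marks = list(line_signals[lines[0]].columns)
    sim = pd.DataFrame(np.eye(len(lines)), index=lines, columns=lines)
    for i, a in enumerate(lines):
        for b in lines[i + 1:]:
            rs = []
            for mark in marks:
                xa = line_signals[a][mark]
                xb = line_signals[b][mark]
                common = xa.dropna().index.intersection(xb.dropna().index)
                rs.append(float(np.corrcoef(xa[common], xb[common])[0, 1]))
            sim.loc[a, b] = sim.loc[b, a] = float(np.mean(rs))
    scores = (sim.sum(axis=1) - 1.0) / (len(lines) - 1)
    best = scores.sort_index().idxmax()  # ties -> lexicographically first
    return str(best), sim
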