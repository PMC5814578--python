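"""Genome characterisation tracks: CpG islands, feature densities,
low-diversity regions.

CpG islands are detected by sliding a large window (default 10 kb,
1-bp shift) along the sequence, computing at every placement the GC
fraction and the observed/expected CpG ratio

    obs/exp = (#CG dinucleotides x window length) / (#C x #G),

then marking the positions covered exclusively by placements that pass
both thresholds; maximal marked runs at least ``minlen`` long are
reported with region-level mean GC and obs/exp.  Feature densities are
counts in nonoverlapping windows (default 500 kb), with intervals
assigned to the window containing their start so that counts conserve
exactly.  Low-diversity regions are maximal runs of consecutive windows
whose SNV count falls strictly below a quantile of the per-window
counts, kept when the run spans at least ``min_span`` bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGIsland",
    "DensityTrack",
    "find_cpg_islands",
    "windowed_density",
    "low_diversity_regions",
    "export_tracks",
    "read_track",
]


@dataclass
class CpGIsland:
    chrom: str
    start: int
    end: int
    obs_exp: float
    gc: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DensityTrack:
    """Counts of features per nonoverlapping window on one chromosome."""

    chrom: str
    window: int
    counts: np.ndarray
    chrom_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.chrom_length is not None:
            expected = -(-self.chrom_length // self.window)
            if len(self.counts) != expected:
                raise ValueError(
                    f"{self.chrom}: {len(self.counts)} windows, expected {expected}"
                )

    def starts(self) -> np.ndarray:
        return np.arange(len(self.counts)) * self.window

    def ends(self) -> np.ndarray:
        ends = self.starts() + self.window
        if self.chrom_length is not None:
            ends = np.minimum(ends, self.chrom_length)
        return ends


def _base_indicators(seq: str):
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cg = is_c[:-1] & is_g[1:] if len(arr) > 1 else np.zeros(0, bool)
    return is_c, is_g, is_cg


def _region_stats(is_c, is_g, is_cg, start: int, end: int) -> tuple[float, float]:
    length = end - start
    c = int(is_c[start:end].sum())
    g = int(is_g[start:end].sum())
    cg = int(is_cg[start : max(start, end - 1)].sum())
    gc = (c + g) / length
    oe = cg * length / (c * g) if c * g > 0 else 0.0
    return oe, gc


def find_cpg_islands(
    seq: str,
    chrom: str = "chr",
    window: int = 10_000,
    shift: int = 1,
    minlen: int = 200,
    min_oe: float = 0.6,
    min_gc: float = 0.5,
) -> list[CpGIsland]:
    """Scan a nucleotide sequence (A/C/G/T/N, case-insensitive) for CpG
    islands.  Returns islands ordered by start; empty (with a warning)
    when the sequence is shorter than the scan window."""
    n = len(seq)
    if window > n:
        warnings.warn(
            f"{chrom}: sequence ({n} bp) shorter than scan window ({window} bp)"
        )
        return []
    if shift < 1 or minlen < 1:
        raise ValueError("shift and minlen must be >= 1")
    is_c, is_g, is_cg = _base_indicators(seq)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(0, n - window + 1, shift)
    c = cum_c[starts + window] - cum_c[starts]
    g = cum_g[starts + window] - cum_g[starts]
    cg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc = (c + g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(c * g > 0, cg * window / np.maximum(c * g, 1), 0.0)
    passing = (gc >= min_gc) & (oe >= min_oe)

    # position p is marked iff every placement covering it passes; a
    # placement starting at t covers [t, t + window)
    fail = ~passing
    cum_fail = np.concatenate([[0], np.cumsum(fail)])
    pos = np.arange(n)
    # covering placement indices k satisfy starts[k] in [p - window + 1, p]
    lo = np.searchsorted(starts, pos - window + 1, side="left")
    hi = np.searchsorted(starts, pos, side="right")
    covered = hi > lo
    marked = covered & ((cum_fail[hi] - cum_fail[lo]) == 0)

    islands: list[CpGIsland] = []
    boundaries = np.flatnonzero(np.diff(marked.astype(np.int8)))
    run_starts = list(boundaries[marked[boundaries + 1]] + 1)
    run_ends = list(boundaries[~marked[boundaries + 1]] + 1)
    if marked.size and marked[0]:
        run_starts.insert(0, 0)
    if marked.size and marked[-1]:
        run_ends.append(n)
    for s, e in zip(run_starts, run_ends):
        if e - s >= minlen:
            oe_r, gc_r = _region_stats(is_c, is_g, is_cg, int(s), int(e))
            islands.append(CpGIsland(chrom, int(s), int(e), oe_r, gc_r))
    return islands


def windowed_density(
    features,
    chrom_length: int,
    window: int = 500_000,
    chrom: str = "chr",
) -> DensityTrack:
    """Counts per nonoverlapping window of ``features``: either point
    positions or (start, end) intervals, the latter assigned to the
    window containing their start (each feature counted exactly once)."""
    if window <= 0:
        raise ValueError("window must be positive")
    arr = np.asarray(features)
    if arr.ndim == 2:
        arr = arr[:, 0]
    arr = arr.astype(np.int64)
    if arr.size and (arr.min() < 0 or arr.max() >= chrom_length):
        bad = arr[(arr < 0) | (arr >= chrom_length)][0]
        raise ValueError(f"feature at {bad} beyond chromosome [0, {chrom_length})")
    n_windows = -(-chrom_length // window)
    counts = np.bincount(arr // window, minlength=n_windows)
    return DensityTrack(chrom=chrom, window=window, counts=counts,
                        chrom_length=chrom_length)


def low_diversity_regions(
    track: DensityTrack,
    density_quantile: float = 0.10,
    min_span: int = 100_000_000,
) -> pd.DataFrame:
    """Maximal runs of windows with counts strictly below the given
    quantile of this track's window counts, spanning >= min_span bp.

    With all windows equal nothing is strictly below the threshold, so no
    region is reported.  Returns (chrom, start, end, span, mean_density).
    """
    counts = track.counts
    if counts.size == 0:
        raise ValueError("empty density track")
    threshold = np.quantile(counts, density_quantile)
    low = counts < threshold
    rows = []
    starts_bp = track.starts()
    ends_bp = track.ends()
    i = 0
    while i < len(low):
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(low) and low[j + 1]:
            j += 1
        start, end = int(starts_bp[i]), int(ends_bp[j])
        if end - start >= min_span:
            rows.append(
                (track.chrom, start, end, end - start,
                 float(counts[i : j + 1].mean()))
            )
        i = j + 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "span", "mean_density"]
    )


def export_tracks(
    tracks: dict[str, Sequence[DensityTrack]],
    islands: Optional[Sequence[CpGIsland]] = None,
    regions: Optional[pd.DataFrame] = None,
    outdir: str | Path = ".",
) -> dict[str, Path]:
    """Write BED-like circos-input tables, one file per track plus
    optional island and low-diversity tables.  Deterministic ordering;
    round-trip safe via :func:`read_track`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, track_list in tracks.items():
        seen = set()
        window_sizes = {t.window for t in track_list}
        if len(window_sizes) > 1:
            raise ValueError(f"track {name!r}: inconsistent window sizes")
        rows = []
        for t in track_list:
            if t.chrom in seen:
                raise ValueError(f"track {name!r}: duplicate chromosome {t.chrom}")
            seen.add(t.chrom)
            for s, e, c in zip(t.starts(), t.ends(), t.counts):
                rows.append((t.chrom, int(s), int(e), int(c)))
        path = outdir / f"density_{name}.bed"
        pd.DataFrame(rows, columns=["chrom", "start", "end", "count"]).to_csv(
            path, sep="\t", index=False, header=False
        )
        written[name] = path
    if islands is not None:
        path = outdir / "cpg_islands.bed"
        rows = [(i.chrom, i.start, i.end, f"{i.obs_exp:.4f}", f"{i.gc:.4f}")
                for i in islands]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
        written["cpg_islands"] = path
    if regions is not None:
        path = outdir / "low_diversity.bed"
        header = "#chrom\tstart\tend\tspan\tmean_density\n"
        with open(path, "w") as fh:
            fh.write(header)
            for row in regions.itertuples(index=False):
                fh.write("\t".join(str(v) for v in row) + "\n")
        written["low_diversity"] = path
    return written


def read_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "count"], dtype={"chrom": str},
    )
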