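"""ROH-island calling on segmented codified SNP matrices.

The input matrix codifies, per individual (row) and SNP marker (column),
whether the marker lies inside a run of homozygosity for that individual
(1) or not (0).  A Bernoulli block segmentation of that matrix yields,
per block, the population frequency p̂ of ROH passing through it.  ROH
*islands* are the blocks where that frequency is unusually high: blocks
whose p̂ reaches the chosen empirical quantile (default 95%) of the
per-marker p̂ distribution are flagged, and adjacent flagged blocks are
merged into one island interval.

Physical structure enters twice.  A marker map (marker name, chromosome,
base-pair position) drives the physical-span regularizer — blocks
shorter than a threshold T (default 1% of the chromosome's span) are
inadmissible — and chromosomes are segmented independently, since a
block cannot cross a chromosome boundary.

Coordinates: marker maps use 1-based base-pair positions on input;
island intervals are emitted 0-based half-open (BED convention), with
the right edge one past the last marker's base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataMatrix
from .errors import ValidationError
from .penalty_selection import FRVConfig, frv_select
from .segmentation import (
    PenaltySpec,
    RohRegularization,
    SegmentationResult,
    fit_dp,
    fit_hierarchical,
)

__all__ = [
    "MarkerMap",
    "ChromosomeFit",
    "IslandCall",
    "default_threshold_mb",
    "segment_by_chromosome",
    "call_islands",
    "islands_only",
    "intersect_islands",
    "write_islands_bed",
    "read_islands_bed",
]


class MarkerMap:
    """Per-column marker name, chromosome, and physical position.

    Positions are 1-based base pairs, strictly increasing within each
    chromosome; chromosome order follows first appearance and all of a
    chromosome's markers must be contiguous.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chrom", "pos"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"marker map missing columns: {sorted(missing)}")
        table = table.reset_index(drop=True)
        table["pos"] = table["pos"].astype(np.int64)
        table["chrom"] = table["chrom"].astype(str)
        if (table["pos"] < 0).any():
            raise ValidationError("marker positions must be non-negative")
        seen: dict = {}
        prev_chrom = None
        for i, (chrom, pos) in enumerate(zip(table["chrom"], table["pos"])):
            if chrom != prev_chrom:
                if chrom in seen:
                    raise ValidationError(
                        f"chromosome {chrom} appears in non-contiguous runs"
                    )
                seen[chrom] = [i, i + 1]
                prev_chrom = chrom
            else:
                if pos <= table["pos"].iloc[i - 1]:
                    raise ValidationError(
                        f"positions not strictly increasing on chromosome "
                        f"{chrom} near row {i + 1}"
                    )
                seen[chrom][1] = i + 1
        self.table = table
        self._ranges = seen  # chrom -> [start_row, end_row) 0-based

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(self._ranges)

    def column_range(self, chrom: str) -> tuple:
        """(lo, hi) 1-based inclusive column range of a chromosome."""
        lo, hi = self._ranges[chrom]
        return lo + 1, hi

    def positions(self, chrom: str) -> np.ndarray:
        lo, hi = self._ranges[chrom]
        return self.table["pos"].to_numpy()[lo:hi]

    @classmethod
    def read(cls, path) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_threshold_mb(marker_map: MarkerMap, chrom: str) -> float:
    """Minimum island span T: 1% of the chromosome's physical extent, in Mb."""
    pos = marker_map.positions(chrom)
    return 0.01 * float(pos[-1] - pos[0]) / 1e6


@dataclass(frozen=True)
class ChromosomeFit:
    """Segmentation of one chromosome's column slice."""

    chrom: str
    col_start: int  # 1-based inclusive, global column index
    col_end: int
    result: SegmentationResult
    selected_lambda: float | None = None  # set when chosen by FRV


def segment_by_chromosome(
    data: DataMatrix,
    marker_map: MarkerMap,
    pen_template: PenaltySpec,
    *,
    solver: str = "hierarchical",
    lam: float | None = None,
    frv_cfg: FRVConfig | None = None,
    threshold_mb: float | str | None = "auto",
    variance_floor: float = 1e-8,
) -> list:
    """Segment each chromosome independently.

    ``threshold_mb``: "auto" sets T to 1% of each chromosome's span and
    activates the physical-span regularizer; a float fixes T in Mb for
    every chromosome; ``None`` keeps the template's regularizer as is
    (e.g. the constant one).  ``lam=None`` selects λ per chromosome by
    FRV; otherwise the given constant is used.
    """
    if len(marker_map) != data.m:
        raise ValidationError(
            f"marker map has {len(marker_map)} rows but the data has "
            f"m={data.m} columns"
        )
    fit_fn = fit_dp if solver == "dp" else fit_hierarchical
    out = []
    for chrom in marker_map.chromosomes:
        lo, hi = marker_map.column_range(chrom)
        sub = data.select_columns(lo, hi)
        pen = pen_template
        if threshold_mb is not None:
            t = (
                default_threshold_mb(marker_map, chrom)
                if threshold_mb == "auto"
                else float(threshold_mb)
            )
            pen = replace(
                pen_template,
                reg=RohRegularization(marker_map.positions(chrom), t),
            )
        if lam is None:
            res = frv_select(
                sub, pen, frv_cfg, variance_floor=variance_floor
            )
            out.append(
                ChromosomeFit(chrom, lo, hi, res.selected_model,
                              selected_lambda=res.selected_lambda)
            )
        else:
            result = fit_fn(
                sub, pen.with_lambda(lam), variance_floor=variance_floor
            )
            out.append(ChromosomeFit(chrom, lo, hi, result))
    return out


@dataclass(frozen=True)
class IslandCall:
    """One contiguous segment with its ROH frequency and island flag.

    ``start_bp``/``end_bp`` are 0-based half-open; the column indices are
    1-based inclusive and global (indices into the full data matrix).
    """

    chrom: str
    start_bp: int
    end_bp: int
    start_col: int
    end_col: int
    p_hat: float
    island: bool

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValidationError(
                f"empty interval [{self.start_bp}, {self.end_bp}) on "
                f"{self.chrom}"
            )


def _as_chrom_fits(result, marker_map: MarkerMap) -> list:
    if isinstance(result, SegmentationResult):
        chroms = marker_map.chromosomes
        if len(chroms) != 1:
            raise ValidationError(
                "a bare SegmentationResult covers one chromosome; this map "
                f"has {len(chroms)} — pass the per-chromosome fits instead"
            )
        if result.m != len(marker_map):
            raise ValidationError(
                f"fit has m={result.m} columns but the map has "
                f"{len(marker_map)} markers"
            )
        return [ChromosomeFit(chroms[0], 1, result.m, result)]
    return list(result)


def call_islands(
    result,
    marker_map: MarkerMap,
    quantile: float = 0.95,
    *,
    weighted: bool = True,
) -> list:
    """Flag high-frequency blocks as ROH islands.

    The cutoff is the empirical ``quantile`` of the fitted block
    frequencies.  With ``weighted=True`` (default) every marker
    contributes its block's p̂, i.e. blocks weigh by their marker count —
    comparable to per-SNP frequency distributions; ``weighted=False``
    takes the quantile over one value per block.  Blocks with
    p̂ ≥ cutoff are flagged and adjacent flagged blocks on the same
    chromosome are merged (merged p̂ is the marker-count-weighted mean).

    ``result`` is a single-chromosome :class:`SegmentationResult` or the
    list of :class:`ChromosomeFit` from :func:`segment_by_chromosome`.
    """
    if not 0.0 < quantile < 1.0:
        raise ValidationError(f"quantile must be in (0, 1), got {quantile}")
    fits = _as_chrom_fits(result, marker_map)
    blocks = []  # (chrom, global r, global s, p_hat, width)
    for cf in fits:
        if cf.result.family != "bernoulli":
            raise ValidationError("island calling requires bernoulli family")
        offset = cf.col_start - 1
        for (r, s), est in zip(
            cf.result.change_points.blocks(), cf.result.block_params
        ):
            blocks.append(
                (cf.chrom, offset + r, offset + s, est.theta["p"], s - r + 1)
            )
    p_vals = np.array([b[3] for b in blocks])
    if weighted:
        widths = np.array([b[4] for b in blocks])
        cutoff = float(np.quantile(np.repeat(p_vals, widths), quantile))
    else:
        cutoff = float(np.quantile(p_vals, quantile))

    pos = marker_map.table["pos"].to_numpy()
    calls = []
    i = 0
    while i < len(blocks):
        chrom, r, s, p, width = blocks[i]
        flagged = p >= cutoff
        if flagged:
            # merge the run of adjacent flagged blocks on this chromosome
            tot_w, acc = width, p * width
            j = i + 1
            while j < len(blocks):
                chrom2, r2, s2, p2, w2 = blocks[j]
                if chrom2 != chrom or p2 < cutoff:
                    break
                s, tot_w, acc = s2, tot_w + w2, acc + p2 * w2
                j = j + 1
            p = acc / tot_w
            i = j
        else:
            i += 1
        calls.append(
            IslandCall(
                chrom=chrom,
                start_bp=int(pos[r - 1]) - 1,
                end_bp=int(pos[s - 1]),
                start_col=r,
                end_col=s,
                p_hat=float(p),
                island=bool(flagged),
            )
        )
    return calls


def islands_only(calls: Sequence[IslandCall]) -> list:
    return [c for c in calls if c.island]


def _total_len(iv: list) -> int:
    return sum(e - s for s, e in iv)


def _intersect_len(a: list, b: list) -> int:
    # both lists sorted and non-overlapping; two-pointer sweep
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def intersect_islands(
    a: Sequence[IslandCall], b: Sequence[IslandCall]
) -> pd.DataFrame:
    """Base-pair overlap summary between two island lists.

    Only entries flagged as islands are compared.  Per chromosome (and a
    final genome-wide row) the table reports total bases in each list, in
    their intersection and union, and the intersection percentage
    100·|a∩b|/|a∪b| (base-pair Jaccard).
    """
    def per_chrom(calls):
        d: dict = {}
        for c in calls:
            if not c.island:
                continue
            if c.end_bp <= c.start_bp:
                raise ValidationError(f"malformed interval on {c.chrom}")
            d.setdefault(c.chrom, []).append((c.start_bp, c.end_bp))
        for iv in d.values():
            iv.sort()
            for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
                if s2 < e1:
                    raise ValidationError("overlapping islands within one list")
        return d

    da, db = per_chrom(a), per_chrom(b)
    rows = []
    tot = {"bp_a": 0, "bp_b": 0, "bp_intersection": 0, "bp_union": 0}
    for chrom in sorted(set(da) | set(db)):
        iva, ivb = da.get(chrom, []), db.get(chrom, [])
        la, lb = _total_len(iva), _total_len(ivb)
        inter = _intersect_len(iva, ivb)
        union = la + lb - inter
        rows.append(
            {
                "chrom": chrom,
                "bp_a": la,
                "bp_b": lb,
                "bp_intersection": inter,
                "bp_union": union,
                "pct_intersection": 100.0 * inter / union if union else 0.0,
            }
        )
        for k, v in zip(tot, (la, lb, inter, union)):
            tot[k] += v
    rows.append(
        {
            "chrom": "genome",
            **tot,
            "pct_intersection": (
                100.0 * tot["bp_intersection"] / tot["bp_union"]
                if tot["bp_union"]
                else 0.0
            ),
        }
    )
    return pd.DataFrame(rows)


def write_islands_bed(calls: Sequence[IslandCall], path) -> None:
    """Write calls as BED3+ lines: chrom, start, end, p̂, flag, columns."""
    with open(path, "wt", encoding="utf-8") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.p_hat:.17g}\t"
                f"{int(c.island)}\t{c.start_col}\t{c.end_col}\n"
            )


def read_islands_bed(path) -> list:
    """Read BED3+ back into IslandCall objects.

    Plain BED3 (external island lists) is accepted: p̂ becomes NaN, the
    island flag True, and column indices 0 (unknown).
    """
    calls = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{line_no}: not a BED line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            p = float(parts[3]) if len(parts) > 3 else float("nan")
            flag = bool(int(parts[4])) if len(parts) > 4 else True
            c0 = int(parts[5]) if len(parts) > 6 else 0
            c1 = int(parts[6]) if len(parts) > 6 else 0
            calls.append(
                IslandCall(chrom, start, end, c0, c1, p, flag)
            )
    return calls


def genome_fit_to_dict(fits: Sequence[ChromosomeFit], marker_map: MarkerMap) -> dict:
    """Serializable document for a per-chromosome segmentation."""
    fits = list(fits)
    return {
        "family": fits[0].result.family,
        "n": fits[0].result.n,
        "chromosomes": [
            {
                "chrom": cf.chrom,
                "col_start": cf.col_start,
                "col_end": cf.col_end,
                "selected_lambda": cf.selected_lambda,
                "result": cf.result.to_dict(
                    positions=marker_map.positions(cf.chrom)
                ),
            }
            for cf in fits
        ],
    }


def genome_fit_from_dict(doc: dict) -> list:
    from .segmentation import segmentation_result_from_dict

    return [
        ChromosomeFit(
            chrom=entry["chrom"],
            col_start=entry["col_start"],
            col_end=entry["col_end"],
            result=segmentation_result_from_dict(entry["result"]),
            selected_lambda=entry.get("selected_lambda"),
        )
        for entry in doc["chromosomes"]
    ]


def write_genome_fit(fits, marker_map, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(genome_fit_to_dict(fits, marker_map), fh, indent=2)


def read_genome_fit(path) -> list:
    with open(path, "rt", encoding="utf-8") as fh:
        return genome_fit_from_dict(json.load(fh))
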