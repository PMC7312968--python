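"""Binary disorder calls, maximal runs, LDR/DBR regions and per-protein summaries.

A residue is called disordered when its predictor score is at or above the
threshold (0.5 by default, inclusive).  A long disordered region (LDR) is a
maximal run of at least ``min_len`` (default 30) consecutive called residues;
a disorder binding region (DBR) is the same rule applied to an ANCHOR-style
binding-propensity track.

Coordinates are half-open 0-based internally; every external output (Region
fields, TSV writers) is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ProteinRecord, ProteomeBundle, ScoreTrack

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_LEN = 30


@dataclass
class Region:
    """A maximal called run on one protein, 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    kind: str  # "LDR" | "DBR"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinDisorderSummary:
    """Per-protein disorder metrics used by the proteome-level aggregation."""

    protein_id: str
    length: int
    n_disordered: int
    pct_disordered: float
    ldrs: list[Region] = field(default_factory=list)
    dbrs: list[Region] = field(default_factory=list)
    binding_missing: bool = False

    @property
    def n_ldr(self) -> int:
        return len(self.ldrs)

    @property
    def n_dbr(self) -> int:
        return len(self.dbrs)

    @property
    def pct_in_ldr(self) -> float:
        return 100.0 * sum(r.length for r in self.ldrs) / self.length

    @property
    def pct_in_dbr(self) -> float:
        return 100.0 * sum(r.length for r in self.dbrs) / self.length

    @property
    def has_ldr(self) -> bool:
        return self.n_ldr >= 1

    @property
    def has_dbr(self) -> bool:
        return self.n_dbr >= 1


def binarize(track: ScoreTrack | np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean mask: True where score >= threshold (inclusive)."""
    scores = track.scores if isinstance(track, ScoreTrack) else np.asarray(track, dtype=float)
    return scores >= threshold


def find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end), 1-based inclusive, sorted.

    Runs are flanked by False or the sequence boundary; their union is
    exactly the set of True positions.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)   # 0-based run starts
    ends = np.flatnonzero(diff == -1)    # 0-based exclusive ends
    return [(int(s) + 1, int(e)) for s, e in zip(starts, ends)]


def _regions(mask: np.ndarray, min_len: int, protein_id: str, kind: str) -> list[Region]:
    return [
        Region(protein_id, start, end, kind)
        for start, end in find_runs(mask)
        if end - start + 1 >= min_len
    ]


def find_ldrs(mask: np.ndarray, min_len: int = DEFAULT_MIN_LEN, protein_id: str = "") -> list[Region]:
    """Long disordered regions: maximal runs of >= min_len called residues."""
    return _regions(mask, min_len, protein_id, "LDR")


def find_dbrs(binding_mask: np.ndarray, min_len: int = DEFAULT_MIN_LEN, protein_id: str = "") -> list[Region]:
    """Disorder binding regions from a binarized binding-propensity mask.

    Mirrors the LDR rule: maximal runs of >= min_len consecutive residues
    with binding score at or above the call threshold.
    """
    return _regions(binding_mask, min_len, protein_id, "DBR")


def summarize_protein(
    record: ProteinRecord,
    disorder_track: ScoreTrack,
    binding_track: ScoreTrack | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
) -> ProteinDisorderSummary:
    """Compute per-protein disorder content, LDRs and (optionally) DBRs."""
    if len(disorder_track) != len(record):
        raise ValueError(f"unattached/mismatched disorder track for {record.id!r}")
    mask = binarize(disorder_track, threshold)
    n_dis = int(mask.sum())
    summary = ProteinDisorderSummary(
        protein_id=record.id,
        length=len(record),
        n_disordered=n_dis,
        pct_disordered=100.0 * n_dis / len(record),
        ldrs=find_ldrs(mask, min_len, record.id),
    )
    if binding_track is None:
        summary.binding_missing = True
    else:
        if len(binding_track) != len(record):
            raise ValueError(f"unattached/mismatched binding track for {record.id!r}")
        summary.dbrs = find_dbrs(binarize(binding_track, threshold), min_len, record.id)
    return summary


def summarize_bundle(
    bundle: ProteomeBundle,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[ProteinDisorderSummary]:
    """Summarize every protein in the bundle that has a disorder track."""
    out = []
    for rec in bundle.records:
        track = bundle.disorder.get(rec.id)
        if track is None:
            continue
        out.append(
            summarize_protein(rec, track, bundle.binding.get(rec.id), threshold, min_len)
        )
    return out


def write_regions_tsv(
    summaries: Sequence[ProteinDisorderSummary], path: str | Path, header: str = ""
) -> None:
    """Region table: protein_id, kind, start, end, length (1-based inclusive)."""
    with open(path, "w") as out:
        if header:
            out.write(header)
        out.write("# coordinates: 1-based inclusive\n")
        out.write("protein_id\tkind\tstart\tend\tlength\n")
        for summary in summaries:
            for region in list(summary.ldrs) + list(summary.dbrs):
                out.write(
                    f"{region.protein_id}\t{region.kind}\t{region.start}"
                    f"\t{region.end}\t{region.length}\n"
                )


def write_summary_tsv(
    summaries: Sequence[ProteinDisorderSummary], path: str | Path, header: str = ""
) -> None:
    with open(path, "w") as out:
        if header:
            out.write(header)
        out.write("# coordinates: 1-based inclusive; percentages of protein length\n")
        out.write(
            "protein_id\tlength\tn_disordered\tpct_disordered\tn_ldr\tpct_in_ldr"
            "\tn_dbr\tpct_in_dbr\thas_ldr\thas_dbr\tbinding_missing\n"
        )
        for s in summaries:
            out.write(
                f"{s.protein_id}\t{s.length}\t{s.n_disordered}\t{s.pct_disordered:.4f}"
                f"\t{s.n_ldr}\t{s.pct_in_ldr:.4f}\t{s.n_dbr}\t{s.pct_in_dbr:.4f}"
                f"\t{int(s.has_ldr)}\t{int(s.has_dbr)}\t{int(s.binding_missing)}\n"
            )
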