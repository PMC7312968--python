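"""Input readers and validation for sequences, score tracks and GO annotations.

Score tracks come in the native dialects of the common disorder predictors:

``disopred3``
    Comment lines start with ``#``; data lines are
    ``<1-based index> <residue> <mark> <score>`` (whitespace separated).
``iupred``
    Comment lines start with ``#``; data lines are
    ``<1-based index> <residue> <score>``.
``espritz``
    One line per residue: ``<mark><TAB><score>`` (no index column).
``anchor``
    Same layout as ``iupred`` but the scores are binding propensities.
``generic_tsv``
    Header ``protein_id<TAB>position<TAB>score`` (optional ``kind`` column),
    1-based positions, many proteins per file.

Multi-protein concatenations of the single-protein dialects are supported:
a comment line whose first token after ``#`` looks like an identifier (e.g.
``# P12345``) starts a new protein.  Single-protein files take their id from
the ``protein_id`` argument or the file name stem.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Non-standard IUPAC one-letter codes removed by default.  The cleaning rule
#: drops whole sequences containing any ambiguous residue; restrict to
#: {"B", "X", "Z"} to reproduce the narrower filter exactly.
AMBIGUOUS_DEFAULT = frozenset("BJOUXZ")

GO_ID_RE = re.compile(r"^GO:\d{7}$")

TRACK_DIALECTS = ("disopred3", "iupred", "espritz", "anchor", "generic_tsv")
ONTOLOGIES = ("BP", "MF", "CC")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ProteinRecord:
    """One protein sequence with a group (genus) label."""

    id: str
    sequence: str
    genus: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise InputError(f"protein {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreTrack:
    """Per-residue scores in [0, 1]: disorder probability or binding propensity."""

    protein_id: str
    kind: str  # "disorder" | "binding"
    predictor: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("disorder", "binding"):
            raise InputError(f"track kind must be 'disorder' or 'binding', got {self.kind!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise InputError(f"track for {self.protein_id!r}: scores must be a non-empty 1-D array")
        if np.any(self.scores < 0.0) or np.any(self.scores > 1.0):
            bad = self.scores[(self.scores < 0.0) | (self.scores > 1.0)][0]
            raise InputError(f"track for {self.protein_id!r}: score {bad} outside [0, 1]")

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class GOAnnotation:
    """One (protein, GO term) association with a positive predictive value."""

    protein_id: str
    go_id: str
    ontology: str  # "BP" | "MF" | "CC"
    ppv: float

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.go_id):
            raise InputError(f"malformed GO id {self.go_id!r}")
        if self.ontology not in ONTOLOGIES:
            raise InputError(f"ontology must be one of {ONTOLOGIES}, got {self.ontology!r}")
        if not (0.0 <= self.ppv <= 1.0):
            raise InputError(f"PPV {self.ppv} outside [0, 1] for {self.protein_id}/{self.go_id}")


@dataclass
class ProteomeBundle:
    """Sequences paired with validated disorder/binding tracks for one group."""

    genus: str
    records: list[ProteinRecord]
    disorder: dict[str, ScoreTrack] = field(default_factory=dict)
    binding: dict[str, ScoreTrack] = field(default_factory=dict)
    missing_disorder: list[str] = field(default_factory=list)
    missing_binding: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def read_fasta(path: str | Path, genus: str = "") -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    The record id is the first whitespace-delimited token of the header.
    Raises :class:`InputError` on a missing or empty file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    text = path.read_text()
    if ">" not in text:
        raise InputError(f"no sequences in {path}")
    if not text.lstrip().startswith(">"):
        raise InputError(f"{path}: sequence data before the first FASTA header")
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), genus=genus)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no sequences in {path}")
    return records


def filter_ambiguous(
    records: Sequence[ProteinRecord],
    ambiguous_letters: Iterable[str] = AMBIGUOUS_DEFAULT,
) -> tuple[list[ProteinRecord], int]:
    """Drop sequences containing any ambiguous residue.

    Returns ``(kept, n_removed)``.  Kept records are the input objects,
    unchanged; a record is removed iff its sequence contains at least one
    letter from *ambiguous_letters*.
    """
    ambiguous = frozenset(letter.upper() for letter in ambiguous_letters)
    kept = [rec for rec in records if not (ambiguous & set(rec.sequence))]
    return kept, len(records) - len(kept)


def _check_score(value: str, lineno: int, path: Path) -> float:
    try:
        score = float(value)
    except ValueError as exc:
        raise InputError(f"{path}:{lineno}: malformed score {value!r}") from exc
    if not (0.0 <= score <= 1.0):
        raise InputError(f"{path}:{lineno}: score {score} outside [0, 1]")
    return score


def _parse_indexed_dialect(
    path: Path, n_fields: int, score_col: int, kind: str, predictor: str,
    default_id: str,
) -> list[ScoreTrack]:
    """Shared parser for the ``#``-commented, 1-based-index dialects."""
    tracks: list[ScoreTrack] = []
    scores: list[float] = []
    current_id = default_id
    expected_index = 1

    def flush() -> None:
        nonlocal scores, expected_index
        if scores:
            tracks.append(ScoreTrack(current_id, kind, predictor, np.array(scores)))
        scores = []
        expected_index = 1

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                token = line.lstrip("#").split()
                # a bare comment separates proteins; a token renames the next one
                flush()
                if token:
                    current_id = token[0]
                continue
            fields = line.split()
            if len(fields) < n_fields:
                raise InputError(f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}")
            try:
                index = int(fields[0])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed residue index {fields[0]!r}") from exc
            if index == 1 and scores:
                flush()  # index reset marks a new protein in concatenated files
            elif index != expected_index:
                raise InputError(
                    f"{path}:{lineno}: non-monotonic residue index {index} (expected {expected_index})"
                )
            scores.append(_check_score(fields[score_col], lineno, path))
            expected_index = index + 1
    flush()
    return tracks


def read_score_track(
    path: str | Path,
    dialect: str,
    protein_id: str | None = None,
    predictor: str | None = None,
) -> list[ScoreTrack]:
    """Read per-residue score tracks in one of the predictor dialects.

    Parameters
    ----------
    path : file to read.
    dialect : one of ``disopred3``, ``iupred``, ``espritz``, ``anchor``,
        ``generic_tsv``.  ``anchor`` yields *binding* tracks, all others
        *disorder* tracks.
    protein_id : id for single-protein files without embedded ids
        (defaults to the file name stem).
    predictor : free-text label stored on the tracks (defaults to *dialect*).
    """
    path = Path(path)
    if dialect not in TRACK_DIALECTS:
        raise InputError(f"unknown dialect {dialect!r}; expected one of {TRACK_DIALECTS}")
    if not path.exists():
        raise InputError(f"score file not found: {path}")
    predictor = predictor or dialect
    default_id = protein_id or path.stem
    kind = "binding" if dialect == "anchor" else "disorder"

    if dialect in ("disopred3", "iupred", "anchor"):
        n_fields = 4 if dialect == "disopred3" else 3
        score_col = 3 if dialect == "disopred3" else 2
        tracks = _parse_indexed_dialect(path, n_fields, score_col, kind, predictor, default_id)
    elif dialect == "espritz":
        scores = []
        with open(path) as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise InputError(f"{path}:{lineno}: expected '<mark>\\t<score>'")
                scores.append(_check_score(fields[1], lineno, path))
        if not scores:
            raise InputError(f"no scores in {path}")
        tracks = [ScoreTrack(default_id, kind, predictor, np.array(scores))]
    else:  # generic_tsv
        frame = pd.read_csv(path, sep="\t", comment="#")
        required = {"protein_id", "position", "score"}
        if not required.issubset(frame.columns):
            raise InputError(f"{path}: generic_tsv needs columns {sorted(required)}")
        tracks = []
        for pid, sub in frame.groupby("protein_id", sort=False):
            sub = sub.sort_values("position")
            positions = sub["position"].to_numpy()
            if not np.array_equal(positions, np.arange(1, len(sub) + 1)):
                raise InputError(f"{path}: positions for {pid!r} are not contiguous from 1")
            track_kind = kind
            if "kind" in sub.columns:
                kinds = set(sub["kind"])
                if len(kinds) != 1:
                    raise InputError(f"{path}: mixed 'kind' values for {pid!r}")
                track_kind = kinds.pop()
            raw_scores = sub["score"].to_numpy(dtype=float)
            if np.any(raw_scores < 0) or np.any(raw_scores > 1):
                raise InputError(f"{path}: score outside [0, 1] for {pid!r}")
            tracks.append(ScoreTrack(str(pid), track_kind, predictor, raw_scores))

    if not tracks:
        raise InputError(f"no scores in {path}")
    return tracks


def attach_tracks(
    records: Sequence[ProteinRecord],
    tracks: Iterable[ScoreTrack],
    genus: str | None = None,
    strict: bool = True,
) -> ProteomeBundle:
    """Pair proteins with their disorder/binding tracks, validating lengths.

    Every track must name a known protein, match its sequence length, and be
    the only track of its kind for that protein.  With ``strict=True``
    (default) any violation raises :class:`InputError`; otherwise violations
    are accumulated in ``bundle.errors`` and the offending tracks dropped —
    never silently.  Proteins lacking a track of either kind are listed in
    ``missing_disorder`` / ``missing_binding``.
    """
    by_id = {rec.id: rec for rec in records}
    if genus is None:
        genus = records[0].genus if records else ""
    bundle = ProteomeBundle(genus=genus, records=list(records))
    for track in tracks:
        problem = None
        rec = by_id.get(track.protein_id)
        if rec is None:
            problem = f"track for unknown protein {track.protein_id!r}"
        elif len(track) != len(rec):
            problem = (
                f"length mismatch for {track.protein_id!r} ({track.kind}): "
                f"track {len(track)} vs sequence {len(rec)}"
            )
        else:
            slot = bundle.disorder if track.kind == "disorder" else bundle.binding
            if track.protein_id in slot:
                problem = f"duplicate {track.kind} track for {track.protein_id!r}"
            else:
                slot[track.protein_id] = track
        if problem is not None:
            if strict:
                raise InputError(problem)
            bundle.errors.append(problem)
    bundle.missing_disorder = [r.id for r in records if r.id not in bundle.disorder]
    bundle.missing_binding = [r.id for r in records if r.id not in bundle.binding]
    return bundle


_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


def read_annotations(
    path: str | Path,
    format: str = "pannzer_tsv",
    ppv_min: float = 0.7,
) -> list[GOAnnotation]:
    """Read GO annotations, keeping rows with PPV strictly above *ppv_min*.

    ``pannzer_tsv`` needs columns ``qpid``, ``goid``, ``ontology``, ``PPV``
    (goid may be bare digits or ``GO:``-prefixed).  ``gaf`` (2.x) rows get
    PPV 1.0.  Duplicate (protein, GO id) pairs collapse to the maximum PPV
    before filtering.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    rows: list[GOAnnotation] = []
    if format == "pannzer_tsv":
        frame = pd.read_csv(path, sep="\t", comment="#")
        required = {"qpid", "goid", "ontology", "PPV"}
        if not required.issubset(frame.columns):
            raise InputError(f"{path}: pannzer_tsv needs columns {sorted(required)}")
        for row in frame.itertuples(index=False):
            goid = str(row.goid)
            if not goid.startswith("GO:"):
                goid = "GO:" + goid.zfill(7)
            onto = str(row.ontology).strip()
            onto = {"biological_process": "BP", "molecular_function": "MF",
                    "cellular_component": "CC"}.get(onto.lower(), onto.upper())
            rows.append(GOAnnotation(str(row.qpid), goid, onto, float(row.PPV)))
    elif format == "gaf":
        with open(path) as handle:
            for raw in handle:
                if raw.startswith("!") or not raw.strip():
                    continue
                fields = raw.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise InputError(f"{path}: GAF line with {len(fields)} columns")
                aspect = _GAF_ASPECT.get(fields[8])
                if aspect is None:
                    raise InputError(f"{path}: unknown GAF aspect {fields[8]!r}")
                rows.append(GOAnnotation(fields[1], fields[4], aspect, 1.0))
    else:
        raise InputError(f"unknown annotation format {format!r}")

    best: dict[tuple[str, str], GOAnnotation] = {}
    for ann in rows:
        key = (ann.protein_id, ann.go_id)
        if key not in best or ann.ppv > best[key].ppv:
            best[key] = ann
    return [ann for ann in best.values() if ann.ppv > ppv_min]
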