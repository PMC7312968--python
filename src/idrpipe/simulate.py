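"""Synthetic paired proteomes with a truth manifest.

The generator emulates the statistical structure the comparative analysis
assumes: per-residue disorder arises from a two-state (ordered/disordered)
Markov chain along the sequence, predictor scores are Beta emissions
conditional on the hidden state, binding-propensity tracks share the state
path (so DBRs correlate with LDRs, as in real data), and GO annotations are
Bernoulli draws whose odds can be multiplied for *planted* terms on truly
disordered proteins of a focal group.

The two-state chain makes the analytic residue-level disorder fraction
available in closed form: with stay probabilities ``p_oo`` and ``p_dd`` the
stationary disordered fraction is ``(1-p_oo) / ((1-p_oo) + (1-p_dd))``, and
the *observed* (score >= 0.5) fraction follows by mixing the two Beta upper
tails — see :func:`expected_disorder_fraction`.

Default stay probabilities per group are set so the observed disorder
fractions sit near 28.2% (focal group) and 34.0% (comparison group), the
regime of a camelid-versus-human proteome comparison, with a mean disordered
run length of 100 residues.

Sequences are uniform over the 20 standard letters: no pipeline stage reads
composition, and modelling the real compositional bias of IDRs is
deliberately out of scope — do not use these sequences to test
composition-aware predictors.

One global seed drives everything; per-protein substreams are derived from
the (seed, group, protein id) triple, so regenerating any single protein is
stable under reordering.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .io import GOAnnotation, ProteinRecord, ScoreTrack

STANDARD_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
AMBIGUOUS_LETTERS = np.array(list("BXZ"))

#: run length >= this in the *true* state path marks a protein as truly disordered
TRUE_LDR_MIN = 30


@dataclass(frozen=True)
class LengthModel:
    """Log-normal protein lengths (median ~350 aa), clipped to [30, 5000]."""

    median: float = 350.0
    sigma: float = 0.45
    min_len: int = 30
    max_len: int = 5000


@dataclass(frozen=True)
class BlockModel:
    """Two-state Markov chain over residues: ordered <-> disordered."""

    p_stay_ordered: float
    p_stay_disordered: float

    def __post_init__(self) -> None:
        for p in (self.p_stay_ordered, self.p_stay_disordered):
            if not (0.0 < p < 1.0):
                raise ValueError(f"stay probability {p} outside (0, 1)")

    @property
    def stationary_disordered(self) -> float:
        leave_o = 1.0 - self.p_stay_ordered
        leave_d = 1.0 - self.p_stay_disordered
        return leave_o / (leave_o + leave_d)


@dataclass(frozen=True)
class StateEmissions:
    """Beta(α, β) score emissions per hidden state."""

    disordered: tuple[float, float] = (8.5, 1.5)   # mean 0.85
    ordered: tuple[float, float] = (1.5, 8.5)      # mean 0.15


@dataclass(frozen=True)
class PlantedTerm:
    """A GO term whose annotation odds are multiplied by *odds_ratio* on
    truly disordered proteins of *focal_group*."""

    go_id: str
    focal_group: str
    odds_ratio: float


@dataclass(frozen=True)
class GOModel:
    n_terms: int = 50
    ontology: str = "BP"
    baseline_p: float = 0.15
    planted: tuple[PlantedTerm, ...] = ()
    ppv_alpha: float = 9.0
    ppv_beta: float = 1.5


# stay probabilities chosen (closed form above + Beta tails) so observed
# disorder fractions land near 28.2% / 34.0%, with mean disordered run
# length 333 residues putting roughly half of all proteins in the
# has-an-LDR class and near one LDR per protein on average
_DEFAULT_BLOCKS = {
    "focal": BlockModel(p_stay_ordered=0.998842, p_stay_disordered=0.997),
    "other": BlockModel(p_stay_ordered=0.998468, p_stay_disordered=0.997),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a paired-proteome simulation."""

    seed: int = 0
    groups: tuple[str, str] = ("Camelus", "Homo_sapiens")
    n_proteins: tuple[int, int] = (500, 500)
    length: LengthModel = LengthModel()
    blocks: tuple[BlockModel, BlockModel] = (
        _DEFAULT_BLOCKS["focal"], _DEFAULT_BLOCKS["other"]
    )
    disorder_emissions: StateEmissions = StateEmissions()
    binding_emissions: StateEmissions = StateEmissions(
        disordered=(5.5, 1.5), ordered=(1.2, 8.0)
    )
    couple_binding: bool = True
    ambiguous_spike_rate: float = 0.02
    go: GOModel = GOModel()

    def __post_init__(self) -> None:
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValueError("need two distinct group labels")
        if any(n < 1 for n in self.n_proteins):
            raise ValueError("n_proteins must be positive")
        if not (0.0 <= self.ambiguous_spike_rate < 1.0):
            raise ValueError("ambiguous_spike_rate outside [0, 1)")
        if not (0.0 < self.go.baseline_p < 1.0):
            raise ValueError("baseline annotation probability outside (0, 1)")
        for term in self.go.planted:
            if term.odds_ratio <= 0:
                raise ValueError(f"odds ratio must be positive for {term.go_id}")
            if term.focal_group not in self.groups:
                raise ValueError(f"planted term {term.go_id}: unknown group {term.focal_group}")

    def block_for(self, group: str) -> BlockModel:
        return self.blocks[self.groups.index(group)]

    def n_for(self, group: str) -> int:
        return self.n_proteins[self.groups.index(group)]


@dataclass
class TruthManifest:
    """Ground truth sufficient to recompute every expected pipeline output.

    ``proteins`` maps protein id to a dict with keys ``length``,
    ``n_true_disordered``, ``true_runs`` (1-based inclusive state runs),
    ``true_ldr_runs`` (those of length >= 30), ``disordered_true``,
    ``spiked``.  ``terms`` maps GO id to annotation counts split by true
    disorder status plus the planted odds ratio (1.0 when null).
    """

    group: str
    proteins: dict[str, dict] = field(default_factory=dict)
    terms: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"group": self.group, "proteins": self.proteins, "terms": self.terms},
            indent=0, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        data = json.loads(text)
        return cls(group=data["group"], proteins=data["proteins"], terms=data["terms"])


@dataclass
class SimulatedProteome:
    group: str
    records: list[ProteinRecord]
    disorder_tracks: list[ScoreTrack]
    binding_tracks: list[ScoreTrack]
    annotations: list[GOAnnotation]
    manifest: TruthManifest


def expected_disorder_fraction(block: BlockModel, emissions: StateEmissions = StateEmissions()) -> float:
    """Analytic stationary fraction of residues with observed score >= 0.5."""
    pi_d = block.stationary_disordered
    tail_d = float(beta_dist.sf(0.5, *emissions.disordered))
    tail_o = float(beta_dist.sf(0.5, *emissions.ordered))
    return pi_d * tail_d + (1.0 - pi_d) * tail_o


def term_ids(n_terms: int) -> list[str]:
    """Sequential synthetic GO ids GO:0000001 ... GO:{n_terms:07d}."""
    return [f"GO:{i:07d}" for i in range(1, n_terms + 1)]


def _protein_rng(seed: int, group: str, protein_id: str, stream: int) -> np.random.Generator:
    key = zlib.crc32(f"{group}/{protein_id}".encode())
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, key, stream])))


def _simulate_states(rng: np.random.Generator, length: int, block: BlockModel) -> np.ndarray:
    """Hidden state path via alternating geometric run lengths."""
    state = bool(rng.random() < block.stationary_disordered)
    mask = np.empty(length, dtype=bool)
    pos = 0
    while pos < length:
        stay = block.p_stay_disordered if state else block.p_stay_ordered
        run = int(rng.geometric(1.0 - stay))
        end = min(pos + run, length)
        mask[pos:end] = state
        pos = end
        state = not state
    return mask


def _emit_scores(rng: np.random.Generator, states: np.ndarray, emissions: StateEmissions) -> np.ndarray:
    scores = np.empty(states.size, dtype=float)
    n_d = int(states.sum())
    if n_d:
        scores[states] = rng.beta(*emissions.disordered, size=n_d)
    if n_d < states.size:
        scores[~states] = rng.beta(*emissions.ordered, size=states.size - n_d)
    return scores


def _true_runs(states: np.ndarray) -> list[list[int]]:
    padded = np.concatenate(([False], states, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    return [[int(s), int(e)] for s, e in zip(starts, ends)]


def simulate_proteome(config: SimulationConfig, group: str) -> SimulatedProteome:
    """Simulate one group's sequences, score tracks, annotations and truth.

    A protein is *truly disordered* when its hidden state path contains a
    disordered run of at least 30 residues; planted GO terms multiply the
    annotation odds on such proteins when this group is their focal group.
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}")
    block = config.block_for(group)
    n = config.n_for(group)
    terms = term_ids(config.go.n_terms)
    planted_here = {
        t.go_id: t.odds_ratio for t in config.go.planted if t.focal_group == group
    }
    unknown = set(planted_here) - set(terms)
    if unknown:
        raise ValueError(f"planted terms outside the term list: {sorted(unknown)}")
    baseline = config.go.baseline_p
    base_odds = baseline / (1.0 - baseline)
    p_planted = {
        go_id: (base_odds * theta) / (1.0 + base_odds * theta)
        for go_id, theta in planted_here.items()
    }

    records: list[ProteinRecord] = []
    disorder_tracks: list[ScoreTrack] = []
    binding_tracks: list[ScoreTrack] = []
    annotations: list[GOAnnotation] = []
    manifest = TruthManifest(group=group)
    term_counts = {
        go_id: {"disordered": 0, "ordered": 0, "odds_ratio": planted_here.get(go_id, 1.0)}
        for go_id in terms
    }

    mu = np.log(config.length.median)
    for i in range(n):
        pid = f"{group}_{i + 1:05d}"
        rng = _protein_rng(config.seed, group, pid, stream=0)
        length = int(np.clip(round(np.exp(rng.normal(mu, config.length.sigma))),
                             config.length.min_len, config.length.max_len))
        states = _simulate_states(rng, length, block)
        disorder_scores = _emit_scores(rng, states, config.disorder_emissions)
        if config.couple_binding:
            binding_states = states
        else:
            binding_states = _simulate_states(rng, length, block)
        binding_scores = _emit_scores(rng, binding_states, config.binding_emissions)

        letters = rng.choice(STANDARD_LETTERS, size=length)
        spiked = bool(rng.random() < config.ambiguous_spike_rate)
        if spiked:
            pos = int(rng.integers(length))
            letters[pos] = rng.choice(AMBIGUOUS_LETTERS)
        sequence = "".join(letters)

        runs = _true_runs(states)
        ldr_runs = [r for r in runs if r[1] - r[0] + 1 >= TRUE_LDR_MIN]
        disordered_true = bool(ldr_runs)

        records.append(ProteinRecord(pid, sequence, genus=group))
        disorder_tracks.append(ScoreTrack(pid, "disorder", "simulated", disorder_scores))
        binding_tracks.append(ScoreTrack(pid, "binding", "simulated", binding_scores))
        manifest.proteins[pid] = {
            "length": length,
            "n_true_disordered": int(states.sum()),
            "true_runs": runs,
            "true_ldr_runs": ldr_runs,
            "disordered_true": disordered_true,
            "spiked": spiked,
        }

        ann_rng = _protein_rng(config.seed, group, pid, stream=1)
        u = ann_rng.random(len(terms))
        ppvs = ann_rng.beta(config.go.ppv_alpha, config.go.ppv_beta, size=len(terms))
        for j, go_id in enumerate(terms):
            p = p_planted.get(go_id, baseline) if disordered_true else baseline
            if u[j] < p:
                annotations.append(
                    GOAnnotation(pid, go_id, config.go.ontology, float(round(ppvs[j], 6)))
                )
                key = "disordered" if disordered_true else "ordered"
                term_counts[go_id][key] += 1

    manifest.terms = term_counts
    return SimulatedProteome(group, records, disorder_tracks, binding_tracks,
                             annotations, manifest)


def simulate_pair(config: SimulationConfig) -> dict[str, SimulatedProteome]:
    """Simulate both groups of a paired comparison under one config."""
    return {group: simulate_proteome(config, group) for group in config.groups}


# ---------------------------------------------------------------------------
# fixture writers (plain-text, byte-deterministic for a fixed config)
# ---------------------------------------------------------------------------

def _write_fasta(records: Sequence[ProteinRecord], path: Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id} genus={rec.genus}\n")
            for k in range(0, len(rec.sequence), 60):
                out.write(rec.sequence[k:k + 60] + "\n")


def _write_indexed(tracks: Sequence[ScoreTrack], path: Path, dialect: str) -> None:
    with open(path, "w") as out:
        for track in tracks:
            out.write(f"# {track.protein_id}\n")
            for i, score in enumerate(track.scores, start=1):
                if dialect == "disopred3":
                    mark = "*" if score >= 0.5 else "."
                    out.write(f"{i:5d} X {mark} {score:.6f}\n")
                else:  # iupred / anchor layout
                    out.write(f"{i}\tX\t{score:.6f}\n")


def _write_generic_tsv(tracks: Sequence[ScoreTrack], path: Path) -> None:
    with open(path, "w") as out:
        out.write("protein_id\tposition\tscore\tkind\n")
        for track in tracks:
            for i, score in enumerate(track.scores, start=1):
                out.write(f"{track.protein_id}\t{i}\t{score:.6f}\t{track.kind}\n")


def _write_pannzer(annotations: Sequence[GOAnnotation], path: Path) -> None:
    with open(path, "w") as out:
        out.write("qpid\tgoid\tontology\tPPV\n")
        for ann in sorted(annotations, key=lambda a: (a.protein_id, a.go_id)):
            out.write(f"{ann.protein_id}\t{ann.go_id[3:]}\t{ann.ontology}\t{ann.ppv:.6f}\n")


def write_fixture_set(
    sim: SimulatedProteome,
    directory: str | Path,
    dialects: Sequence[str] = ("iupred", "generic_tsv"),
) -> dict[str, str]:
    """Write one simulated group as plain-text files; returns {role: path}.

    Emits FASTA, disorder tracks in each requested dialect (``disopred3``,
    ``iupred`` or ``generic_tsv``), binding tracks in the ``anchor`` dialect,
    PANNZER-style annotations and the truth manifest (JSON).  Output bytes
    are a pure function of the simulation config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = sim.group
    files: dict[str, str] = {}

    fasta = directory / f"{g}.fasta"
    _write_fasta(sim.records, fasta)
    files["fasta"] = str(fasta)

    for dialect in dialects:
        path = directory / f"{g}.disorder.{dialect}.txt"
        if dialect in ("disopred3", "iupred"):
            _write_indexed(sim.disorder_tracks, path, dialect)
        elif dialect == "generic_tsv":
            _write_generic_tsv(sim.disorder_tracks, path)
        else:
            raise ValueError(f"unsupported fixture dialect {dialect!r}")
        files[f"disorder_{dialect}"] = str(path)

    anchor = directory / f"{g}.binding.anchor.txt"
    _write_indexed(sim.binding_tracks, anchor, "iupred")
    files["binding_anchor"] = str(anchor)

    ann = directory / f"{g}.annotations.tsv"
    _write_pannzer(sim.annotations, ann)
    files["annotations"] = str(ann)

    truth = directory / f"{g}.truth.json"
    truth.write_text(sim.manifest.to_json())
    files["truth"] = str(truth)
    return files


# ---------------------------------------------------------------------------
# tiny worked example reproducing the published contingency-table layout
# ---------------------------------------------------------------------------

@dataclass
class WorkedExample:
    """Synthetic fixture reproducing a published 2x2 table for one GO term.

    Two groups with 322 and 211 annotated proteins; 111 and 2 of them
    disordered, giving marginals 113/420 by disorder status, 322/211 by
    group and grand total 533.
    """

    go_id: str
    labels: tuple[str, str]
    annotationsA: list[GOAnnotation]
    annotationsB: list[GOAnnotation]
    disorderedA: set[str]
    disorderedB: set[str]


def make_tiny_worked_example() -> WorkedExample:
    """Fixture for the sensory-perception term GO:0050911 worked example
    (cells 111/2 disordered, 211/209 not, by group)."""
    go_id = "GO:0050911"
    labels = ("Camelus", "Homo_sapiens")
    idsA = [f"cam_{i:04d}" for i in range(1, 323)]
    idsB = [f"hum_{i:04d}" for i in range(1, 212)]
    return WorkedExample(
        go_id=go_id,
        labels=labels,
        annotationsA=[GOAnnotation(pid, go_id, "BP", 0.9) for pid in idsA],
        annotationsB=[GOAnnotation(pid, go_id, "BP", 0.9) for pid in idsB],
        disorderedA=set(idsA[:111]),
        disorderedB=set(idsB[:2]),
    )
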