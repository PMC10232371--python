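"""EF-hand motif scanning and lanmodulin candidate screening.

Lanmodulins (LanMs) are small lanthanide-binding proteins recognizable from
sequence alone by a compact arrangement of four EF-hand motifs: 12-residue
carboxylate-rich metal-binding loops whose adjacent pairs are separated by
only 12-13 residues (against ~25 in classical calcium sensors), usually with
a proline at the second loop position.  This module scans sequences for such
loops, applies the candidate-curation rules (length, hand count, inter-hand
spacing, P2 hallmark), computes basic sequence properties (average molecular
weight, molar extinction coefficient at 280 nm), and builds percent-identity
thresholded sequence similarity networks (SSNs) whose connected components
approximate sequence families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinRecord",
    "EFHandHit",
    "CandidateCall",
    "ScreenCriteria",
    "SimilarityNetwork",
    "DEFAULT_LOOP_PATTERN",
    "LOOP_LENGTH",
    "read_fasta",
    "write_fasta",
    "scan_ef_hands",
    "classify_lanm",
    "sequence_properties",
    "global_identity",
    "build_ssn",
    "connected_clusters",
]

LOOP_LENGTH = 12

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED = CANONICAL | {"X"}

#: Default EF-hand loop position classes (1-based position within the loop).
#: Position 1 is the monodentate Asn/Asp ligand, 3 and 5 the first shell
#: carboxylates/hydroxyls and 12 the C-terminal bidentate Glu/Asp.  X never
#: matches a constrained position.  All classes are overridable per call.
DEFAULT_LOOP_PATTERN: dict[int, frozenset[str]] = {
    1: frozenset("DN"),
    3: frozenset("DNE"),
    5: frozenset("DNEST"),
    12: frozenset("DE"),
}

#: Ligand classes reported per hit (position 9 is a frequent sidechain ligand
#: even though the default scan leaves it unconstrained).
LIGAND_REPORT_CLASSES: dict[int, frozenset[str]] = {
    **DEFAULT_LOOP_PATTERN,
    9: frozenset("DNEST"),
}

# Average (isotope-abundance weighted) residue masses, Da; +H2O for the chain.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.0153
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)


class SequenceInputError(ValueError):
    """Raised for empty sequences or letters outside the accepted alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier (uppercase one-letter codes)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    def validate(self) -> None:
        if not self.sequence:
            raise SequenceInputError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - EXTENDED
        if bad:
            raise SequenceInputError(
                f"{self.id}: invalid letters {sorted(bad)} (canonical 20 + X allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EFHandHit:
    """One matched 12-residue EF-hand loop.

    ``loop_start`` is the 1-based index of loop position 1; ``p2`` flags a
    proline at loop position 2 (the LanM hallmark); ``ligand_pattern`` records
    which of the reporting positions {1, 3, 5, 9, 12} carry a residue of the
    expected ligand class.
    """

    loop_start: int
    loop_positions: str
    p2: bool
    ligand_pattern: dict[int, bool] = field(compare=False)

    @property
    def loop_end(self) -> int:
        """1-based index of loop position 12."""
        return self.loop_start + LOOP_LENGTH - 1


@dataclass
class ScreenCriteria:
    """Toggles for the LanM candidate-curation rules.

    Defaults mirror the curation used for the family census: mature length
    under 200 residues, at least four EF hands, at least one adjacent pair of
    hands separated by fewer than 14 residues.  ``require_p2`` (at least one
    hand with proline at loop position 2) is a hallmark of the family and is
    on by default but reported as its own criterion.  ``exact_hands`` switches
    the hand-count rule from ">= min_hands" to "== min_hands".
    """

    max_length: int = 200
    min_hands: int = 4
    exact_hands: bool = False
    max_spacing: int = 13
    require_p2: bool = True


@dataclass
class CandidateCall:
    id: str
    n_ef_hands: int
    min_adjacent_spacing: int | None
    has_p2: bool
    length_ok: bool
    verdict: bool
    reasons: list[str]


@dataclass
class SimilarityNetwork:
    """Undirected percent-identity network over sequence records."""

    nodes: list[str]
    edges: list[tuple[str, str, float, float]]  # (id_a, id_b, pid, score)
    threshold: float

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, pid, score in self.edges:
            g.add_edge(a, b, percent_identity=pid, alignment_score=score)
        return g

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tpercent_identity\talignment_score\n")
            for a, b, pid, score in self.edges:
                fh.write(f"{a}\t{b}\t{pid:.4f}\t{score:.2f}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


def read_fasta(path) -> list[ProteinRecord]:
    records = [ProteinRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    for r in records:
        r.validate()
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def scan_ef_hands(
    record: ProteinRecord,
    pattern: dict[int, frozenset[str]] | None = None,
) -> list[EFHandHit]:
    """Find all non-overlapping left-greedy EF-hand loop matches.

    The scan slides a 12-residue window left to right; a window matches when
    every constrained loop position holds a residue of its class (X never
    matches).  On a match the window advances past the loop, so hits never
    overlap and are returned sorted by ``loop_start`` (1-based).
    """
    record.validate()
    if len(record) < LOOP_LENGTH:
        raise SequenceInputError(
            f"{record.id}: sequence shorter than one EF-hand loop ({LOOP_LENGTH})"
        )
    if pattern is None:
        pattern = DEFAULT_LOOP_PATTERN
    seq = record.sequence
    hits: list[EFHandHit] = []
    i = 0
    while i <= len(seq) - LOOP_LENGTH:
        window = seq[i : i + LOOP_LENGTH]
        if all(window[pos - 1] in allowed for pos, allowed in pattern.items()):
            ligands = {
                pos: window[pos - 1] in cls
                for pos, cls in LIGAND_REPORT_CLASSES.items()
            }
            hits.append(
                EFHandHit(
                    loop_start=i + 1,
                    loop_positions=window,
                    p2=window[1] == "P",
                    ligand_pattern=ligands,
                )
            )
            i += LOOP_LENGTH
        else:
            i += 1
    return hits


def adjacent_spacings(hits: list[EFHandHit]) -> list[int]:
    """Residues strictly between loop i's position 12 and loop i+1's position 1."""
    return [b.loop_start - a.loop_end - 1 for a, b in zip(hits, hits[1:])]


def classify_lanm(
    record: ProteinRecord,
    hits: list[EFHandHit],
    criteria: ScreenCriteria | None = None,
) -> CandidateCall:
    """Apply the LanM curation rules to a scanned record.

    A failing verdict is a result, not an error; ``reasons`` lists every
    criterion that failed.  The classification is a pure function of its
    arguments.
    """
    if criteria is None:
        criteria = ScreenCriteria()
    reasons: list[str] = []

    length_ok = len(record) < criteria.max_length
    if not length_ok:
        reasons.append("length")

    n = len(hits)
    if criteria.exact_hands:
        hands_ok = n == criteria.min_hands
    else:
        hands_ok = n >= criteria.min_hands
    if not hands_ok:
        reasons.append("n_ef_hands")

    spacings = adjacent_spacings(hits)
    min_spacing = min(spacings) if spacings else None
    if min_spacing is None or min_spacing > criteria.max_spacing:
        reasons.append("spacing")

    has_p2 = any(h.p2 for h in hits)
    if criteria.require_p2 and not has_p2:
        reasons.append("p2")

    return CandidateCall(
        id=record.id,
        n_ef_hands=n,
        min_adjacent_spacing=min_spacing,
        has_p2=has_p2,
        length_ok=length_ok,
        verdict=not reasons,
        reasons=reasons,
    )


def sequence_properties(record: ProteinRecord) -> dict:
    """Length, average molecular weight (Da) and ε280 (M⁻¹cm⁻¹).

    MW is the sum of average residue masses plus one water.  The extinction
    coefficient follows the Trp/Tyr/cystine increments used by ProtParam:
    ε280 = 5500·nTrp + 1490·nTyr + 125·n_cystine; cysteines are assumed
    reduced (n_cystine = 0) unless ``n_cystine`` says otherwise.  X residues
    contribute the mean canonical residue mass and set ``mw_approximate``.
    """
    return composition_properties(record.sequence, record_id=record.id)


def composition_properties(sequence: str, *, n_cystine: int = 0, record_id: str = "") -> dict:
    seq = sequence.upper()
    bad = set(seq) - EXTENDED
    if bad:
        raise SequenceInputError(f"{record_id}: invalid letters {sorted(bad)}")
    n_x = seq.count("X")
    mw = sum(_RESIDUE_MASS.get(aa, _MEAN_RESIDUE_MASS) for aa in seq) + _WATER_MASS
    if n_x:
        warnings.warn(
            f"{record_id or 'sequence'}: {n_x} X residue(s); MW uses the mean "
            "canonical residue mass and is approximate",
            stacklevel=2,
        )
    eps = 5500 * seq.count("W") + 1490 * seq.count("Y") + 125 * n_cystine
    return {
        "length": len(seq),
        "molecular_weight": mw,
        "epsilon_280": float(eps),
        "mw_approximate": bool(n_x),
    }


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    *,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
) -> dict:
    """Needleman-Wunsch global percent identity and alignment score.

    Identity denominator is the alignment length after stripping terminal-gap
    columns (internal gaps count; overhangs do not).  The pair is aligned in
    a canonical order so the result is symmetric in its arguments.
    """
    for rec in (a, b):
        rec.validate()
    # canonical order makes the traceback (and hence identity) symmetric
    first, second = (a, b) if (a.sequence, a.id) <= (b.sequence, b.id) else (b, a)
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    alignment = aligner.align(first.sequence, second.sequence)[0]
    s1, s2 = str(alignment[0]), str(alignment[1])
    # strip terminal gap columns
    start = 0
    end = len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    core1, core2 = s1[start:end], s2[start:end]
    identities = sum(x == y and x != "-" for x, y in zip(core1, core2))
    length = len(core1)
    pid = 100.0 * identities / length if length else 0.0
    return {"percent_identity": pid, "alignment_score": float(alignment.score)}


def build_ssn(
    records: list[ProteinRecord],
    threshold: float,
    *,
    score_floor: float = 0.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
) -> SimilarityNetwork:
    """All-vs-all identity network, keeping edges at or above ``threshold``.

    The alignment-score floor stands in for a database E-value cut: pairs
    must both clear the identity threshold and score above ``score_floor``.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    if not records:
        raise ValueError("at least one record required")
    edges = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            res = global_identity(
                a, b, gap_open=gap_open, gap_extend=gap_extend, matrix=matrix
            )
            if res["percent_identity"] >= threshold and res["alignment_score"] > score_floor:
                edges.append((a.id, b.id, res["percent_identity"], res["alignment_score"]))
    return SimilarityNetwork(
        nodes=[r.id for r in records], edges=edges, threshold=threshold
    )


def rethreshold(network: SimilarityNetwork, threshold: float) -> SimilarityNetwork:
    """Raise the identity threshold of an existing network without realigning."""
    if threshold < network.threshold:
        raise ValueError("can only raise the threshold of a computed network")
    return SimilarityNetwork(
        nodes=list(network.nodes),
        edges=[e for e in network.edges if e[2] >= threshold],
        threshold=threshold,
    )


def connected_clusters(network: SimilarityNetwork) -> list[set[str]]:
    """Connected components of the network, largest first (ties by member id)."""
    comps = list(nx.connected_components(network.to_graph()))
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def candidate_table(calls: list[CandidateCall]):
    """Candidate calls as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [c.id for c in calls],
            "n_ef_hands": [c.n_ef_hands for c in calls],
            "min_spacing": [c.min_adjacent_spacing for c in calls],
            "has_p2": [c.has_p2 for c in calls],
            "length_ok": [c.length_ok for c in calls],
            "verdict": ["pass" if c.verdict else "fail" for c in calls],
            "reasons": [";".join(c.reasons) for c in calls],
        }
    )
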