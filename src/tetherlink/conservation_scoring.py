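"""Position-wise conservation scoring for protein and DNA alignments.

Protein columns are scored with an entropy score over a reduced
seven-class amino-acid alphabet: residues are mapped to physicochemical
types, and a column's score is

    score = 1 - H / ln(7),

with H the Shannon entropy (natural log) of the type frequencies among
non-gap residues.  An invariant column scores 1; a column spread evenly
over all seven types scores 0.  Highly conserved positions are
conventionally framed at score > 0.9.

DNA columns are scored by per-column information content, 2 - H2 bits
(H2 the base-2 entropy of base frequencies) — the stack-height basis of
sequence logos.

The default seven-class partition groups {AVLIMC} aliphatic/sulfur,
{FWYH} aromatic, {STNQ} polar, {KR} basic, {DE} acidic, {G}, {P}; it is
one member of the reduced-alphabet family and fully overridable — no
byte-compatibility with any external scoring tool is claimed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from io import StringIO
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, ParameterError

__all__ = [
    "SEVEN_TYPE_PARTITION",
    "AlignmentProfile",
    "SyntheticMsaParams",
    "entropic_conservation",
    "dna_information_content",
    "frame_conserved",
    "profile_from_alignment",
    "score_alignment",
    "generate_msa",
    "logo_matrix",
    "msa_to_fasta",
]

GAP = "-"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

SEVEN_TYPE_PARTITION: Tuple[str, ...] = (
    "AVLIMC",  # aliphatic + sulfur-containing
    "FWYH",    # aromatic
    "STNQ",    # polar uncharged
    "KR",      # basic
    "DE",      # acidic
    "G",
    "P",
)


def _residue_to_type(partition: Sequence[str]) -> Dict[str, int]:
    mapping: Dict[str, int] = {}
    for k, members in enumerate(partition):
        for aa in members:
            if aa in mapping:
                raise ParameterError(
                    f"residue {aa!r} occurs in more than one type class"
                )
            mapping[aa] = k
    return mapping


def entropic_conservation(
    column_counts: Mapping[str, int],
    type_partition: Sequence[str] = SEVEN_TYPE_PARTITION,
) -> Optional[float]:
    """Entropy-based conservation of one protein column, in [0, 1].

    Gaps are excluded from the frequency vector; an all-gap column has no
    defined score and returns ``None`` (such columns are never framed as
    conserved).  Residues outside the partition raise an error.
    """
    mapping = _residue_to_type(type_partition)
    n_types = len(type_partition)
    type_counts = np.zeros(n_types, dtype=float)
    for sym, count in column_counts.items():
        if count < 0:
            raise ParameterError(f"negative count for symbol {sym!r}")
        if count == 0 or sym == GAP:
            continue
        if sym not in mapping:
            raise AlphabetError(f"residue {sym!r} not in the type partition")
        type_counts[mapping[sym]] += count
    total = type_counts.sum()
    if total == 0:
        return None  # all-gap column: undefined score
    freqs = type_counts[type_counts > 0] / total
    entropy = float(-(freqs * np.log(freqs)).sum())
    score = 1.0 - entropy / math.log(n_types)
    return min(max(score, 0.0), 1.0)


def dna_information_content(column_counts: Mapping[str, int]) -> float:
    """Per-column information content 2 - H2, in bits (logo stack height)."""
    counts = np.array(
        [column_counts.get(b, 0) for b in DNA_ALPHABET], dtype=float
    )
    for sym in column_counts:
        if sym not in DNA_ALPHABET and sym != GAP:
            raise AlphabetError(f"unexpected DNA symbol {sym!r}")
    total = counts.sum()
    if total == 0:
        raise ParameterError("DNA column has zero observations")
    freqs = counts[counts > 0] / total
    h2 = float(-(freqs * np.log2(freqs)).sum())
    return 2.0 - h2


def frame_conserved(
    scores: Sequence[Optional[float]], threshold: float = 0.9
) -> List[int]:
    """1-based positions with score strictly above the framing threshold.

    Columns with an undefined score (all-gap) are never framed.
    """
    return [
        i + 1
        for i, s in enumerate(scores)
        if s is not None and s > threshold
    ]


@dataclass
class AlignmentProfile:
    """Per-column symbol counts and conservation scores for one MSA."""

    columns: List[Counter]
    alphabet: str  # "protein" | "dna"
    n_sequences: int
    scores: List[Optional[float]] = field(default_factory=list)
    low_confidence: List[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.columns)


def profile_from_alignment(
    alignment: Union[str, MultipleSeqAlignment], alphabet: str = "protein"
) -> AlignmentProfile:
    """Column-count profile of an aligned FASTA text or alignment object."""
    if isinstance(alignment, str):
        alignment = AlignIO.read(StringIO(alignment), "fasta")
    n = len(alignment)
    if n == 0:
        raise ParameterError("alignment has no sequences")
    length = alignment.get_alignment_length()
    columns = [Counter(str(alignment[:, j]).upper()) for j in range(length)]
    return AlignmentProfile(columns=columns, alphabet=alphabet, n_sequences=n)


def score_alignment(
    alignment: Union[str, MultipleSeqAlignment, AlignmentProfile],
    alphabet: str = "protein",
    type_partition: Sequence[str] = SEVEN_TYPE_PARTITION,
    gap_flag_fraction: float = 0.5,
) -> AlignmentProfile:
    """Score every column of an alignment.

    Protein alignments get the entropic seven-type score; DNA alignments
    get information content in bits (gaps excluded from base counts).
    Columns with more than ``gap_flag_fraction`` gaps are flagged
    low-confidence.
    """
    profile = (
        alignment
        if isinstance(alignment, AlignmentProfile)
        else profile_from_alignment(alignment, alphabet)
    )
    scores: List[Optional[float]] = []
    flags: List[bool] = []
    for col in profile.columns:
        gap_fraction = col.get(GAP, 0) / profile.n_sequences
        flags.append(gap_fraction > gap_flag_fraction)
        if profile.alphabet == "protein":
            scores.append(entropic_conservation(col, type_partition))
        elif profile.alphabet == "dna":
            non_gap = {s: c for s, c in col.items() if s != GAP}
            scores.append(
                dna_information_content(non_gap) if non_gap else None
            )
        else:
            raise ParameterError(f"unknown alphabet {profile.alphabet!r}")
    profile.scores = scores
    profile.low_confidence = flags
    return profile


@dataclass
class SyntheticMsaParams:
    """Generative parameters for a synthetic alignment with known
    per-column substitution rates.

    ``consensus`` is the column template; ``substitution_probs`` gives,
    per column, the probability that a sequence deviates from the
    consensus symbol (replaced by a uniformly random other symbol).
    A scalar applies to every column.
    """

    n_sequences: int
    length: int
    alphabet: str = "protein"
    consensus: Optional[str] = None
    substitution_probs: Union[float, Sequence[float]] = 0.1
    gap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ParameterError("n_sequences and length must be >= 1")
        if self.alphabet not in ("protein", "dna"):
            raise ParameterError(f"unknown alphabet {self.alphabet!r}")
        probs = np.atleast_1d(np.asarray(self.substitution_probs, dtype=float))
        if np.any((probs < 0) | (probs > 1)):
            raise ParameterError("substitution probabilities outside [0, 1]")
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ParameterError("gap_prob outside [0, 1]")
        if self.consensus is not None and len(self.consensus) != self.length:
            raise ParameterError("consensus length does not match `length`")


def generate_msa(params: SyntheticMsaParams) -> MultipleSeqAlignment:
    """Seeded synthetic MSA with column-wise known substitution rates."""
    rng = np.random.default_rng(params.seed)
    symbols = PROTEIN_ALPHABET if params.alphabet == "protein" else DNA_ALPHABET
    consensus = params.consensus
    if consensus is None:
        consensus = "".join(
            rng.choice(list(symbols), size=params.length)
        )
    probs = np.broadcast_to(
        np.atleast_1d(np.asarray(params.substitution_probs, dtype=float)),
        (params.length,),
    )
    rows = []
    for s in range(params.n_sequences):
        chars = []
        for j in range(params.length):
            if rng.random() < params.gap_prob:
                chars.append(GAP)
            elif rng.random() < probs[j]:
                alternatives = [c for c in symbols if c != consensus[j]]
                chars.append(alternatives[rng.integers(len(alternatives))])
            else:
                chars.append(consensus[j])
        rows.append(
            SeqRecord(Seq("".join(chars)), id=f"seq_{s:04d}", description="")
        )
    return MultipleSeqAlignment(rows)


def logo_matrix(profile: AlignmentProfile) -> List[Dict[str, float]]:
    """Per-column symbol heights for a sequence logo.

    For DNA columns the stack height is the information content and each
    base's letter height is its frequency times that stack height, the
    convention standard logo renderers use.  Protein columns use the
    entropic conservation score as stack height.  Returns one mapping
    per column: ``{"position": p, "<symbol>": height, ...}``.
    """
    if not profile.scores:
        profile = score_alignment(profile, profile.alphabet)
    symbols = DNA_ALPHABET if profile.alphabet == "dna" else PROTEIN_ALPHABET
    rows: List[Dict[str, float]] = []
    for pos, (col, score) in enumerate(
        zip(profile.columns, profile.scores), start=1
    ):
        non_gap = sum(c for s, c in col.items() if s != GAP)
        row: Dict[str, float] = {"position": pos}
        for sym in symbols:
            freq = col.get(sym, 0) / non_gap if non_gap else 0.0
            row[sym] = freq * score if score is not None else 0.0
        rows.append(row)
    return rows


def msa_to_fasta(alignment: MultipleSeqAlignment) -> str:
    """Serialize an alignment as aligned FASTA text."""
    out = StringIO()
    AlignIO.write(alignment, out, "fasta")
    return out.getvalue()
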