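"""Distillation of aligned protein families into ordered triplet tokens.

A protein family's multiple sequence alignment is reduced to the columns
that are well occupied across the family (gap fraction at most a
threshold); each member's residues at those columns, read in order and
grouped three at a time, form its *distilled sequence* of amino-acid
triplet tokens. Triplets — not single residues — are the vocabulary unit
of the protein language model, and gap characters are legitimate token
characters (a token like ``"A-D"`` records an indel inside a retained
window). Masked-language-model training instances are produced from the
distilled corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = set(AMINO_ACIDS) | {GAP}

MASK_TOKEN = "<MASK>"
PAD_TOKEN = "<PAD>"
UNK_TOKEN = "<UNK>"
SPECIAL_TOKENS = (PAD_TOKEN, MASK_TOKEN, UNK_TOKEN)


class InputError(ValueError):
    """Invalid user-supplied data."""


@dataclass(frozen=True)
class AlignedFamily:
    """One family's MSA: equal-length rows over the amino-acid alphabet + '-'."""

    family_id: str
    member_ids: list[str]
    aligned_rows: list[str]

    def __post_init__(self):
        if not self.aligned_rows:
            raise InputError(f"family {self.family_id!r} has no members")
        if len(self.member_ids) != len(self.aligned_rows):
            raise InputError("member_ids and aligned_rows length mismatch")
        n = len(self.aligned_rows[0])
        for mid, row in zip(self.member_ids, self.aligned_rows):
            if len(row) != n:
                raise InputError(f"row {mid!r} has length {len(row)} != {n}")
            bad = set(row) - ALPHABET
            if bad:
                raise InputError(f"row {mid!r} contains invalid characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_rows[0])

    def row(self, member_id: str) -> str:
        try:
            return self.aligned_rows[self.member_ids.index(member_id)]
        except ValueError:
            raise KeyError(f"member {member_id!r} not in family {self.family_id!r}") from None


@dataclass(frozen=True)
class ColumnSelection:
    retained: tuple[int, ...]
    max_gap_fraction: float

    def __post_init__(self):
        if list(self.retained) != sorted(set(self.retained)):
            raise InputError("retained columns must be strictly ascending")


@dataclass(frozen=True)
class DistilledSequence:
    family_id: str
    member_id: str
    triplets: tuple[str, ...]

    def __post_init__(self):
        for t in self.triplets:
            if len(t) != 3:
                raise InputError(f"triplet {t!r} does not have length 3")

    def __len__(self) -> int:
        return len(self.triplets)


@dataclass
class TripletVocabulary:
    """Bijective token <-> id map with reserved PAD/MASK/UNK ids 0/1/2."""

    token_to_id: dict[str, int] = field(default_factory=dict)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD_TOKEN]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK_TOKEN]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK_TOKEN]

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __post_init__(self):
        if not self.token_to_id:
            self.token_to_id = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
        ids = list(self.token_to_id.values())
        if len(set(ids)) != len(ids):
            raise InputError("token_to_id is not a bijection")

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    def encode(self, triplets: Sequence[str]) -> np.ndarray:
        unk = self.unk_id
        return np.array([self.token_to_id.get(t, unk) for t in triplets], dtype=np.intp)

    def decode(self, ids: Sequence[int]) -> list[str]:
        rev = self.id_to_token
        return [rev[int(i)] for i in ids]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.token_to_id, indent=0, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TripletVocabulary":
        return cls(token_to_id=json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MlmInstance:
    input_ids: np.ndarray
    target_positions: np.ndarray
    target_ids: np.ndarray
    mask_rate: float


# ---------------------------------------------------------------------------

def select_columns(family: AlignedFamily, max_gap_fraction: float = 0.5) -> ColumnSelection:
    """Retain alignment columns whose gap fraction is <= ``max_gap_fraction``.

    This is the occupancy criterion standing in for "evolutionarily
    important positions": columns present in most members carry the
    family's conserved signal, columns that are mostly gaps are dropped.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise InputError("max_gap_fraction must lie in [0, 1]")
    rows = np.array([list(r) for r in family.aligned_rows])
    gap_fraction = (rows == GAP).mean(axis=0)
    retained = tuple(int(i) for i in np.flatnonzero(gap_fraction <= max_gap_fraction))
    return ColumnSelection(retained=retained, max_gap_fraction=max_gap_fraction)


def distill(family: AlignedFamily, member_id: str,
            selection: ColumnSelection) -> DistilledSequence:
    """Read the member's residues at the retained columns and group them
    into consecutive triplets; a trailing partial group is padded with '-'."""
    row = family.row(member_id)
    chars = [row[c] for c in selection.retained]
    while len(chars) % 3:
        chars.append(GAP)
    triplets = tuple("".join(chars[i:i + 3]) for i in range(0, len(chars), 3))
    return DistilledSequence(family_id=family.family_id, member_id=member_id,
                             triplets=triplets)


def distill_family(family: AlignedFamily,
                   max_gap_fraction: float = 0.5) -> list[DistilledSequence]:
    sel = select_columns(family, max_gap_fraction)
    return [distill(family, m, sel) for m in family.member_ids]


def build_vocabulary(corpus: Iterable[DistilledSequence],
                     min_count: int = 1) -> TripletVocabulary:
    """Map every triplet with corpus frequency >= min_count to a unique id;
    rarer triplets encode to UNK."""
    counts: dict[str, int] = {}
    empty = True
    for seq in corpus:
        empty = False
        for t in seq.triplets:
            counts[t] = counts.get(t, 0) + 1
    if empty:
        raise InputError("corpus is empty")
    vocab = TripletVocabulary()
    for token in sorted(counts):
        if counts[token] >= min_count:
            vocab.token_to_id[token] = len(vocab.token_to_id)
    return vocab


def mask_for_mlm(seq: DistilledSequence, vocab: TripletVocabulary, rate: float,
                 rng: np.random.Generator) -> MlmInstance:
    """Corrupt exactly ``round(rate * n)`` positions (at least 1 when
    rate > 0) with the MASK token, chosen uniformly without replacement."""
    if not 0.0 <= rate <= 1.0:
        raise InputError("mask rate must lie in [0, 1]")
    ids = vocab.encode(seq.triplets)
    n = len(ids)
    if n < 1:
        raise InputError("cannot mask an empty sequence")
    n_mask = int(round(rate * n))
    if rate > 0:
        n_mask = max(n_mask, 1)
    positions = np.sort(rng.choice(n, size=n_mask, replace=False)).astype(np.intp)
    corrupted = ids.copy()
    targets = ids[positions].copy()
    corrupted[positions] = vocab.mask_id
    return MlmInstance(input_ids=corrupted, target_positions=positions,
                       target_ids=targets, mask_rate=rate)


# ---- I/O ------------------------------------------------------------------

def read_alignment(path: str | Path, family_id: str | None = None,
                   fmt: str | None = None) -> AlignedFamily:
    """Read an aligned FASTA or Stockholm file; '.' gaps are normalized to '-'."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return AlignedFamily(
        family_id=family_id or path.stem,
        member_ids=[rec.id for rec in aln],
        aligned_rows=[str(rec.seq).upper().replace(".", GAP) for rec in aln],
    )


def write_alignment_fasta(family: AlignedFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mid, row in zip(family.member_ids, family.aligned_rows):
            fh.write(f">{mid}\n{row}\n")


def write_distilled_tsv(corpus: Iterable[DistilledSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tmember_id\ttriplets\n")
        for seq in corpus:
            fh.write(f"{seq.family_id}\t{seq.member_id}\t{' '.join(seq.triplets)}\n")


def read_distilled_tsv(path: str | Path) -> list[DistilledSequence]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family_id"):
            raise InputError(f"{path}: missing distilled-corpus header")
        for line in fh:
            fam, member, trip = line.rstrip("\n").split("\t")
            out.append(DistilledSequence(fam, member, tuple(trip.split(" "))))
    return out
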