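"""Data model, parsing, tokenization and filtering for peptide affinity datasets.

The central record type is :class:`AffinityRecord`: one allele--peptide
measurement with an IC50 value in nM and an inequality qualifier.  Quantitative
records carry an exact IC50 (``inequality == Inequality.EQ``); qualitative
records carry only a censoring bound (``LT`` or ``GT``), e.g. a non-binder
known only as "IC50 > 50000 nM".

Peptides are strings over the 20 canonical amino acids.  The alphabet policy
is strict: ambiguous residues (B, J, O, U, X, Z) are rejected rather than
wild-carded, since a silently substituted residue would corrupt an affinity
regression.  Tokenization prepends a BOS (begin-of-sequence) token so the
recurrent model has a defined start state; peptides are read N- to C-terminus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetically ordered single-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)


class Inequality(str, Enum):
    """Qualifier on an IC50 measurement: exact, below bound, or above bound."""

    EQ = "="
    LT = "<"
    GT = ">"


class MeasurementKind(str, Enum):
    quantitative = "quant"
    qualitative = "qual"


def validate_peptide(peptide: str) -> None:
    """Raise ``ValueError`` naming position and character if invalid."""
    if not peptide:
        raise ValueError("peptide is empty")
    for pos, ch in enumerate(peptide):
        if ch not in _AA_SET:
            raise ValueError(
                f"invalid character {ch!r} at position {pos} in peptide "
                f"{peptide!r}; allowed alphabet is the 20 canonical amino acids"
            )


@dataclass(frozen=True)
class AffinityRecord:
    """One allele--peptide binding measurement.

    Parameters
    ----------
    allele_id : str
        Opaque allele identifier, e.g. ``"HLA-A-0201"``.
    peptide : str
        Uppercase sequence over the 20-letter amino-acid alphabet.
    ic50_nm : float
        IC50 in nM; for qualitative records this is the censoring bound.
    inequality : Inequality
        ``EQ`` for exact measurements, ``LT``/``GT`` for censored bounds.
    kind : MeasurementKind
        Quantitative records must be ``EQ``; qualitative must be ``LT``/``GT``.
    """

    allele_id: str
    peptide: str
    ic50_nm: float
    inequality: Inequality = Inequality.EQ
    kind: MeasurementKind = MeasurementKind.quantitative

    def __post_init__(self) -> None:
        validate_peptide(self.peptide)
        if self.peptide != self.peptide.upper():
            raise ValueError("peptide must be uppercase")
        if not (self.ic50_nm > 0):
            raise ValueError(f"ic50_nm must be positive, got {self.ic50_nm}")
        if self.kind is MeasurementKind.quantitative:
            if self.inequality is not Inequality.EQ:
                raise ValueError("quantitative records must have inequality '='")
        else:
            if self.inequality is Inequality.EQ:
                raise ValueError(
                    "qualitative records must carry a bound ('<' or '>')"
                )


@dataclass(frozen=True)
class RowRejection:
    """A rejected input row with the reason, for audit trails."""

    row_index: int
    reason: str
    row: Mapping[str, object]


class Vocabulary:
    """Token/index bijection over the amino-acid alphabet plus PAD and BOS.

    PAD has the reserved index 0, BOS index 1, residues follow in the order of
    :data:`AMINO_ACIDS`; total size 22.
    """

    PAD = "<pad>"
    BOS = "<bos>"

    def __init__(self) -> None:
        self.tokens: tuple[str, ...] = (self.PAD, self.BOS) + tuple(AMINO_ACIDS)
        self._index = {tok: i for i, tok in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def bos_index(self) -> int:
        return 1

    def index_of(self, token: str) -> int:
        return self._index[token]

    def token_of(self, index: int) -> str:
        return self.tokens[index]


#: Module-level default vocabulary; the mapping is fixed, so sharing is safe.
DEFAULT_VOCAB = Vocabulary()


@dataclass(frozen=True)
class EncodedPeptide:
    """Token-index form of a peptide: ``[BOS] + residue indices``.

    ``length`` counts non-PAD tokens and equals ``len(peptide) + 1``.
    """

    indices: tuple[int, ...]
    length: int


def tokenize(peptide: str, vocab: Vocabulary = DEFAULT_VOCAB) -> EncodedPeptide:
    """Encode a peptide as ``[BOS] + per-residue indices``."""
    validate_peptide(peptide)
    idx = (vocab.bos_index,) + tuple(vocab.index_of(ch) for ch in peptide)
    return EncodedPeptide(indices=idx, length=len(peptide) + 1)


def detokenize(encoded: EncodedPeptide, vocab: Vocabulary = DEFAULT_VOCAB) -> str:
    """Inverse of :func:`tokenize`; PAD positions (beyond ``length``) ignored."""
    toks = encoded.indices[1 : encoded.length]
    return "".join(vocab.token_of(i) for i in toks)


@dataclass
class PaddedBatch:
    """Rectangular token-index block with true lengths carried alongside.

    ``indices`` has shape (batch, max_length) padded with the PAD index;
    downstream pooling must only ever read the first ``lengths[b]`` positions
    of row ``b``.
    """

    indices: np.ndarray
    lengths: np.ndarray

    def __len__(self) -> int:
        return self.indices.shape[0]


def pad_batch(
    encoded: Sequence[EncodedPeptide], vocab: Vocabulary = DEFAULT_VOCAB
) -> PaddedBatch:
    """Pad a list of encoded peptides into one rectangular index block."""
    if len(encoded) == 0:
        raise ValueError("pad_batch requires a nonempty list")
    lengths = np.array([e.length for e in encoded], dtype=np.int64)
    width = int(lengths.max())
    block = np.full((len(encoded), width), vocab.pad_index, dtype=np.int64)
    for b, e in enumerate(encoded):
        block[b, : e.length] = e.indices[: e.length]
    return PaddedBatch(indices=block, lengths=lengths)


def unpad_batch(
    batch: PaddedBatch, vocab: Vocabulary = DEFAULT_VOCAB
) -> list[str]:
    """Recover the original peptides from a padded batch."""
    out = []
    for b in range(len(batch)):
        enc = EncodedPeptide(
            indices=tuple(int(i) for i in batch.indices[b]),
            length=int(batch.lengths[b]),
        )
        out.append(detokenize(enc, vocab))
    return out


# ---------------------------------------------------------------------------
# Affinity tables
# ---------------------------------------------------------------------------

#: Canonical column names of the affinity-table dialect.
STANDARD_COLUMNS = ("allele", "peptide", "ic50_nM", "inequality", "kind")

_INEQ_ALIASES = {
    "=": Inequality.EQ, "eq": Inequality.EQ, "": Inequality.EQ,
    "<": Inequality.LT, "lt": Inequality.LT,
    ">": Inequality.GT, "gt": Inequality.GT,
}
_KIND_ALIASES = {
    "quant": MeasurementKind.quantitative,
    "quantitative": MeasurementKind.quantitative,
    "qual": MeasurementKind.qualitative,
    "qualitative": MeasurementKind.qualitative,
}


def read_affinity_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[AffinityRecord], list[RowRejection]]:
    """Read a delimited (comma or tab) affinity table.

    Parameters
    ----------
    path : path
        CSV/TSV file with a header row.
    dialect : mapping, optional
        Maps the canonical column names (``allele``, ``peptide``, ``ic50_nM``,
        ``inequality``, ``kind``) to the file's actual column names, for
        foreign exports whose headers differ.  ``inequality`` and ``kind``
        may be omitted from the file entirely (default: quantitative, ``=``).

    Returns
    -------
    (records, rejections)
        Malformed rows (unparseable IC50, alphabet violations, inconsistent
        qualifiers) become :class:`RowRejection` entries and are also logged;
        they are never silently dropped.

    Raises
    ------
    KeyError
        If a required column cannot be resolved, naming the column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    dialect = dict(dialect or {})
    colmap = {std: dialect.get(std, std) for std in STANDARD_COLUMNS}
    for std in ("allele", "peptide", "ic50_nM"):
        if colmap[std] not in df.columns:
            raise KeyError(
                f"required column {colmap[std]!r} (for {std!r}) not found in "
                f"{path.name}; available: {list(df.columns)}"
            )

    records: list[AffinityRecord] = []
    rejections: list[RowRejection] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            ic50_raw = row[colmap["ic50_nM"]]
            try:
                ic50 = float(ic50_raw)
            except ValueError:
                raise ValueError(f"unparseable IC50 {ic50_raw!r}") from None
            ineq_raw = str(row.get(colmap["inequality"], "=")).strip().lower()
            ineq = _INEQ_ALIASES.get(ineq_raw)
            if ineq is None:
                raise ValueError(f"unknown inequality qualifier {ineq_raw!r}")
            kind_raw = str(row.get(colmap["kind"], "quant")).strip().lower()
            kind = _KIND_ALIASES.get(kind_raw)
            if kind is None:
                raise ValueError(f"unknown measurement kind {kind_raw!r}")
            rec = AffinityRecord(
                allele_id=str(row[colmap["allele"]]).strip(),
                peptide=str(row[colmap["peptide"]]).strip(),
                ic50_nm=ic50,
                inequality=ineq,
                kind=kind,
            )
        except ValueError as exc:
            logger.warning("rejecting row %d of %s: %s", i, path.name, exc)
            rejections.append(RowRejection(row_index=i, reason=str(exc), row=row))
            continue
        records.append(rec)
    logger.info(
        "read %d records (%d rejected) from %s", len(records), len(rejections),
        path,
    )
    return records, rejections


def write_affinity_table(records: Iterable[AffinityRecord], path: str | Path) -> None:
    """Serialize records back to the canonical CSV dialect (lossless inverse)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "allele": [r.allele_id for r in records],
            "peptide": [r.peptide for r in records],
            "ic50_nM": [r.ic50_nm for r in records],
            "inequality": [r.inequality.value for r in records],
            "kind": [r.kind.value for r in records],
        }
    )
    df.to_csv(path, index=False)


def filter_by_length(
    records: Sequence[AffinityRecord], min_len: int, max_len: int
) -> list[AffinityRecord]:
    """Keep records with ``min_len <= len(peptide) <= max_len``, order preserved."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in records if min_len <= len(r.peptide) <= max_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info(
            "filter_by_length(%d, %d): removed %d of %d records",
            min_len, max_len, removed, len(records),
        )
    return kept


def read_fasta_peptides(path: str | Path) -> list[str]:
    """Read sequences from a FASTA file as plain uppercase strings."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def read_peptide_lines(path: str | Path) -> list[str]:
    """Read a peptide-per-line text corpus, skipping blank lines."""
    with open(path) as fh:
        return [ln.strip().upper() for ln in fh if ln.strip()]
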