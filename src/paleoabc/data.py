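"""Heterochronous DNA alignments: fixed-length sequences with per-sample ages.

The observed-data object of the package is a multiple alignment of mtDNA
sequences in which every sample carries a calibrated age (calendar years
before present) and a deme label (the population / mtDNA clade it belongs
to).  Ages are always stored in calendar years BP; conversion to coalescent
generations happens in :mod:`paleoabc.demography`.

``N`` characters mark missing data.  They are carried through I/O unchanged
and excluded pairwise from difference counts downstream (pairwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN"
N_CODE = 4
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

METADATA_COLUMNS = ("id", "age_calBP", "deme", "clade")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ``ACGTN`` string as a uint8 vector (A=0,C=1,G=2,T=3,N=4)."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(raw.shape, 255, dtype=np.uint8)
    for ch, code in _CODE.items():
        out[raw == ord(ch)] = code
    if (out == 255).any():
        bad = chr(raw[int(np.argmax(out == 255))])
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


@dataclass(frozen=True)
class SequenceSample:
    """One aligned sequence with its age (cal yr BP) and deme label."""

    id: str
    sequence: str
    age: float
    deme: str
    clade: str | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"sample {self.id!r}: age must be >= 0, got {self.age}")
        encode_sequence(self.sequence)  # validates the alphabet


class HeterochronousAlignment:
    """Fixed-length alignment of heterochronous samples.

    Internally the alignment is a ``(n, L)`` uint8 matrix plus parallel
    metadata arrays; :class:`SequenceSample` views are materialised on
    demand.  This keeps the simulation pipeline free of per-sequence string
    handling.
    """

    def __init__(self, samples: Iterable[SequenceSample]):
        samples = list(samples)
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sample id {dup!r}")
        lengths = {len(s.sequence) for s in samples}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        matrix = (
            np.stack([encode_sequence(s.sequence) for s in samples])
            if samples
            else np.zeros((0, 0), dtype=np.uint8)
        )
        self._init_arrays(
            matrix,
            ids,
            np.array([s.age for s in samples], dtype=float),
            [s.deme for s in samples],
            [s.clade for s in samples],
        )

    def _init_arrays(self, matrix, ids, ages, demes, clades) -> None:
        if (ages < 0).any():
            raise ValueError("ages must be >= 0")
        self._matrix = np.ascontiguousarray(matrix, dtype=np.uint8)
        self._ids = list(ids)
        self._ages = np.asarray(ages, dtype=float)
        self._demes = list(demes)
        self._clades = list(clades)

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        ids: Sequence[str],
        ages: Sequence[float],
        demes: Sequence[str],
        clades: Sequence[str | None] | None = None,
    ) -> "HeterochronousAlignment":
        """Fast constructor from an encoded uint8 matrix (no string round trip)."""
        obj = cls.__new__(cls)
        if clades is None:
            clades = [None] * len(ids)
        if len({len(ids), matrix.shape[0], len(ages), len(demes), len(clades)}) != 1:
            raise ValueError("metadata lengths do not match matrix rows")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if matrix.size and matrix.max() > N_CODE:
            raise ValueError("matrix codes must be in 0..4")
        obj._init_arrays(matrix, ids, np.asarray(ages, float), list(demes), list(clades))
        return obj

    # -- basic container protocol ------------------------------------------
    @property
    def n(self) -> int:
        return len(self._ids)

    @property
    def L(self) -> int:
        return self._matrix.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def ages(self) -> np.ndarray:
        return self._ages.copy()

    @property
    def deme_labels(self) -> list[str]:
        return list(self._demes)

    @property
    def demes(self) -> list[str]:
        """Deme labels in order of first appearance."""
        return list(dict.fromkeys(self._demes))

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> SequenceSample:
        return SequenceSample(
            id=self._ids[i],
            sequence=decode_sequence(self._matrix[i]),
            age=float(self._ages[i]),
            deme=self._demes[i],
            clade=self._clades[i],
        )

    def __iter__(self) -> Iterator[SequenceSample]:
        return (self[i] for i in range(self.n))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeterochronousAlignment):
            return NotImplemented
        return (
            self._ids == other._ids
            and self._demes == other._demes
            and self._clades == other._clades
            and np.array_equal(self._ages, other._ages)
            and np.array_equal(self._matrix, other._matrix)
        )

    def __repr__(self) -> str:
        return f"<HeterochronousAlignment n={self.n} L={self.L} demes={self.demes}>"

    # -- operations --------------------------------------------------------
    def subset(self, idx: Sequence[int]) -> "HeterochronousAlignment":
        idx = list(idx)
        return HeterochronousAlignment.from_matrix(
            self._matrix[idx],
            [self._ids[i] for i in idx],
            self._ages[idx],
            [self._demes[i] for i in idx],
            [self._clades[i] for i in idx],
        )

    def group_by_deme(self) -> Mapping[str, "HeterochronousAlignment"]:
        """Partition the alignment by deme label (first-appearance order)."""
        groups: dict[str, list[int]] = {}
        for i, d in enumerate(self._demes):
            groups.setdefault(d, []).append(i)
        return {d: self.subset(ix) for d, ix in groups.items()}


def group_by_deme(alignment: HeterochronousAlignment) -> Mapping[str, HeterochronousAlignment]:
    return alignment.group_by_deme()


def read_dataset(fasta_path, metadata_path) -> HeterochronousAlignment:
    """Read a FASTA alignment plus its sample-metadata TSV.

    The TSV is tab-delimited UTF-8 with header ``id  age_calBP  deme  clade``
    and ``#`` comment lines permitted.  Every FASTA record must have a
    metadata row; FASTA order is preserved.
    """
    meta = pd.read_csv(
        metadata_path,
        sep="\t",
        comment="#",
        dtype={"id": str, "deme": str},
        encoding="utf-8",
        float_precision="round_trip",
    )
    missing_cols = set(METADATA_COLUMNS[:3]) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if "clade" not in meta.columns:
        meta["clade"] = None
    meta = meta.set_index("id", verify_integrity=True)

    samples = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise ValueError(f"sample {rec.id!r} present in FASTA but absent from metadata")
        row = meta.loc[rec.id]
        clade = row["clade"]
        if pd.isna(clade):
            clade = None
        samples.append(
            SequenceSample(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                age=float(row["age_calBP"]),
                deme=str(row["deme"]),
                clade=clade,
            )
        )
    return HeterochronousAlignment(samples)


def write_dataset(alignment: HeterochronousAlignment, fasta_path, metadata_path) -> None:
    """Write FASTA + metadata TSV (the inverse of :func:`read_dataset`)."""
    records = [
        SeqRecord(Seq(decode_sequence(alignment.matrix[i])), id=alignment.ids[i], description="")
        for i in range(alignment.n)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for s in alignment:
        rows.append((s.id, s.age, s.deme, "" if s.clade is None else s.clade))
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    df.to_csv(metadata_path, sep="\t", index=False, encoding="utf-8")
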