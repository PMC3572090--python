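"""In-memory containers for aligned haploid sequences and Y-STR profiles.

Both containers carry a per-record population label, which is the grouping
unit for every downstream statistic. Sequences are pre-aligned haplotypes
(mtDNA hypervariable-region segments in the motivating application); STR
profiles are integer repeat counts at a fixed, ordered panel of loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, AlphabetError, EmptyDatasetError, ValidationError

SEQUENCE_ALPHABET = frozenset("ACGT-N")

#: Sentinel for a missing STR repeat count (stored internally; "NA" on disk).
MISSING_REPEAT = -1


@dataclass(frozen=True)
class SequenceRecord:
    sample_id: str
    population: str
    sequence: str


@dataclass
class SequenceDataset:
    """Aligned haploid sequences with population labels.

    Parameters
    ----------
    records
        One :class:`SequenceRecord` per sampled individual, order preserved
        from the source file.
    region_label
        Free-text label for the sequenced region, e.g. ``"HVR1"`` or
        ``"HVR1+HVR2"``. Metadata only; the code never indexes by genomic
        coordinate.
    """

    records: list[SequenceRecord]
    region_label: str = "region"

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyDatasetError("SequenceDataset requires at least one record")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have differing lengths {sorted(lengths)}; input must be aligned"
            )
        for r in self.records:
            if not r.population:
                raise ValidationError(f"record {r.sample_id!r} has an empty population label")
            bad = set(r.sequence) - SEQUENCE_ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {r.sample_id!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population, None)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.records:
            sizes[r.population] = sizes.get(r.population, 0) + 1
        return sizes

    def subset(self, indices) -> "SequenceDataset":
        return SequenceDataset([self.records[i] for i in indices], self.region_label)

    def restrict_to(self, populations) -> "SequenceDataset":
        keep = set(populations)
        return SequenceDataset(
            [r for r in self.records if r.population in keep], self.region_label
        )

    def sequences_of(self, population: str) -> list[str]:
        return [r.sequence for r in self.records if r.population == population]

    def to_int_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Encode as (codes, valid) arrays of shape (n, L).

        codes: uint8 mapping A,C,G,T -> 0..3, '-' -> 4, 'N' -> 5.
        valid: True where the character is a called base (A/C/G/T).
        """
        mapping = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
        n, length = len(self.records), self.alignment_length
        codes = np.empty((n, length), dtype=np.uint8)
        for i, r in enumerate(self.records):
            codes[i] = [mapping[c] for c in r.sequence]
        valid = codes < 4
        return codes, valid


@dataclass
class StrRecord:
    sample_id: str
    population: str
    repeats: tuple[int, ...]


@dataclass
class StrDataset:
    """Y-STR repeat-count profiles at an ordered panel of loci.

    Missing calls are stored as :data:`MISSING_REPEAT`; records carrying any
    missing locus are excluded from distance computations (with a warning)
    rather than being treated as allele 0, because 0 is a legal allele label.
    """

    loci: list[str]
    records: list[StrRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValidationError("StrDataset requires at least one locus")
        if not self.records:
            raise EmptyDatasetError("StrDataset requires at least one record")
        n_loci = len(self.loci)
        for r in self.records:
            if len(r.repeats) != n_loci:
                raise ValidationError(
                    f"record {r.sample_id!r} has {len(r.repeats)} repeat counts, "
                    f"expected {n_loci}"
                )
            if not r.population:
                raise ValidationError(f"record {r.sample_id!r} has an empty population label")
            for v in r.repeats:
                if v < 0 and v != MISSING_REPEAT:
                    raise ValidationError(
                        f"record {r.sample_id!r} has negative repeat count {v}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population, None)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.records:
            sizes[r.population] = sizes.get(r.population, 0) + 1
        return sizes

    def subset(self, indices) -> "StrDataset":
        return StrDataset(self.loci, [self.records[i] for i in indices])

    def restrict_to(self, populations) -> "StrDataset":
        keep = set(populations)
        return StrDataset(self.loci, [r for r in self.records if r.population in keep])

    def has_missing(self) -> bool:
        return any(MISSING_REPEAT in r.repeats for r in self.records)

    def complete(self) -> "StrDataset":
        """Drop records with any missing repeat count (warns if it drops)."""
        kept = [r for r in self.records if MISSING_REPEAT not in r.repeats]
        n_dropped = len(self.records) - len(kept)
        if n_dropped:
            warnings.warn(
                f"excluding {n_dropped} STR record(s) with missing repeat counts "
                "from distance computations",
                stacklevel=2,
            )
        return StrDataset(self.loci, kept)

    def to_matrix(self) -> np.ndarray:
        return np.array([r.repeats for r in self.records], dtype=np.int64)
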