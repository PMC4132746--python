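"""Dual-index DNA barcode sets with guaranteed pairwise edit distance.

Pooled ligation products are tagged twice: a well-specific barcode
delivered by the forward PCR primer (read as the first bases of the
sequencing read) and a plate-specific barcode delivered by the reverse
primer (read as the index read).  Every barcode in a set differs from
every other by a minimum Levenshtein distance so that sequencing errors
are detected, and single errors can be rescued unambiguously.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import edlib

__all__ = [
    "BarcodeSet",
    "BarcodeCapacityError",
    "UNASSIGNED",
    "edit_distance",
    "generate_barcodes",
    "dual_capacity",
    "assign_barcode",
]

UNASSIGNED = -1


class BarcodeCapacityError(ValueError):
    """Requested barcode set is infeasible for the given length/constraints."""


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (substitutions, insertions, deletions)."""
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class BarcodeSet:
    """An ordered set of same-length DNA barcodes.

    role is "well" (forward-primer barcode) or "plate" (reverse-primer /
    index-read barcode).
    """

    barcodes: list[str]
    length: int
    min_edit_distance: int
    role: str = "well"
    _exact: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(len(b) != self.length for b in self.barcodes):
            raise ValueError("all barcodes must have the declared length")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes in set")
        self._exact = {b: i for i, b in enumerate(self.barcodes)}

    def __len__(self) -> int:
        return len(self.barcodes)

    def __getitem__(self, i: int) -> str:
        return self.barcodes[i]

    def validate(self) -> None:
        """Brute-force all-pairs check of the minimum edit distance."""
        for a, b in itertools.combinations(self.barcodes, 2):
            d = edit_distance(a, b)
            if d < self.min_edit_distance:
                raise ValueError(
                    f"barcodes {a} and {b} at distance {d} < "
                    f"{self.min_edit_distance}"
                )


def _passes_composition(
    bc: str, gc_min: float, gc_max: float, max_homopolymer: int
) -> bool:
    gc = 100.0 * (bc.count("G") + bc.count("C")) / len(bc)
    if not (gc_min <= gc <= gc_max):
        return False
    run = 1
    for a, b in zip(bc, bc[1:]):
        run = run + 1 if a == b else 1
        if run > max_homopolymer:
            return False
    return True


def generate_barcodes(
    n: int,
    length: int,
    min_edit: int = 2,
    seed: int = 0,
    role: str = "well",
    gc_min: float = 25.0,
    gc_max: float = 75.0,
    max_homopolymer: int = 3,
) -> BarcodeSet:
    """Greedily build *n* barcodes of *length* nt at pairwise Levenshtein
    distance >= *min_edit*.

    All 4^length k-mers are shuffled deterministically by *seed*; each is
    accepted if it satisfies the composition constraints (GC within
    [gc_min, gc_max] percent, homopolymer runs <= max_homopolymer) and is
    compatible with every barcode accepted so far.

    Raises BarcodeCapacityError when the request is infeasible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 4:
        raise ValueError("length must be >= 4")
    if min_edit > length:
        raise BarcodeCapacityError(
            f"min_edit {min_edit} exceeds barcode length {length}"
        )
    rng = random.Random(seed)
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=length)]
    rng.shuffle(kmers)
    accepted: list[str] = []
    for bc in kmers:
        if not _passes_composition(bc, gc_min, gc_max, max_homopolymer):
            continue
        if all(edit_distance(bc, other) >= min_edit for other in accepted):
            accepted.append(bc)
            if len(accepted) == n:
                return BarcodeSet(accepted, length, min_edit, role)
    raise BarcodeCapacityError(
        f"only {len(accepted)} of {n} barcodes of length {length} "
        f"achievable at min edit distance {min_edit}"
    )


def dual_capacity(wells: BarcodeSet, plates: BarcodeSet) -> int:
    """Number of distinct (well, plate) sample assignments."""
    return len(wells) * len(plates)


def assign_barcode(observed: str, bc_set: BarcodeSet, max_dist: int = 1) -> int:
    """Resolve an observed sequence to a barcode index.

    Exact matches win immediately.  Otherwise the observed sequence is
    assigned to the single barcode within edit distance <= max_dist; if
    none or more than one qualifies the read is UNASSIGNED.
    """
    if not observed:
        raise ValueError("observed barcode is empty")
    hit = bc_set._exact.get(observed)
    if hit is not None:
        return hit
    candidate = UNASSIGNED
    for i, bc in enumerate(bc_set.barcodes):
        if edlib.align(observed, bc, task="distance", k=max_dist)["editDistance"] != -1:
            if candidate != UNASSIGNED:
                return UNASSIGNED  # ambiguous
            candidate = i
    return candidate
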