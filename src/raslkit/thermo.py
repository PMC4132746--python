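"""Nearest-neighbor DNA thermodynamics for probe quality control.

Melting temperatures use the unified DNA/DNA nearest-neighbor parameter
set (SantaLucia-style two-state model) with the entropy-based monovalent
salt correction.  Secondary-structure metrics (hairpin, self-dimer, 3'
end stability) are computed by exhaustive enumeration of ungapped
complementary stems, which is exact for oligo-length inputs.

All temperatures are in degrees Celsius, free energies in kcal/mol,
salt in mM, strand concentration in nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ThermoParams",
    "ThermoReport",
    "InvalidSequenceError",
    "gc_percent",
    "melting_temperature",
    "duplex_tm",
    "end_stability_dg",
    "structure_report",
    "reverse_complement",
]

R_GAS = 1.987  # cal / (mol K)
T_KELVIN = 273.15
ABSOLUTE_ZERO_C = -273.15  # reported when no structure exists

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Unified DNA/DNA nearest-neighbor parameters: stack -> (dH kcal/mol, dS cal/mol/K).
# Keyed by the 5'->3' dinucleotide on one strand; the antiparallel complement
# stack is thermodynamically identical and is folded into the same entry.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex initiation terms per terminal base pair.
_INIT = {
    "A": (2.3, 4.1), "T": (2.3, 4.1),
    "G": (0.1, -2.8), "C": (0.1, -2.8),
}


class InvalidSequenceError(ValueError):
    """Raised for empty, non-ACGT, or too-short sequences."""


@dataclass(frozen=True)
class ThermoParams:
    """Solution conditions for the two-state duplex model.

    nn_table : name of the nearest-neighbor parameter set (only the
        unified DNA/DNA table is implemented).
    monovalent_salt : Na+ concentration in mM.
    oligo_conc : total strand concentration in nM (the two strands are
        assumed equimolar, so C_T/4 enters the Tm equation).
    temperature_ref : temperature in C at which dG is evaluated.
    """

    nn_table: str = "santalucia_unified"
    monovalent_salt: float = 50.0
    oligo_conc: float = 50.0
    temperature_ref: float = 37.0

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0 mM")
        if self.oligo_conc <= 0:
            raise ValueError("oligo_conc must be > 0 nM")


@dataclass(frozen=True)
class ThermoReport:
    """Thermodynamic QC metrics for one oligo."""

    tm: float
    gc_percent: float
    hairpin_tm: float
    self_any_tm: float
    self_end_tm: float
    end_stability_dg: float  # |dG| of the 3'-terminal pentamer duplex


DEFAULT_PARAMS = ThermoParams()


def _validate(seq: str, min_len: int = 1) -> str:
    if not seq:
        raise InvalidSequenceError("empty sequence")
    seq = seq.upper()
    if any(b not in "ACGT" for b in seq):
        raise InvalidSequenceError(f"non-ACGT characters in sequence {seq!r}")
    if len(seq) < min_len:
        raise InvalidSequenceError(
            f"sequence of length {len(seq)} shorter than minimum {min_len}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """Percent G+C of *seq* (0-100)."""
    seq = _validate(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def _nn_sums(seq: str) -> tuple[float, float]:
    """(dH, dS) of the perfect duplex of seq, including initiation."""
    dh, ds = 0.0, 0.0
    for a, b in zip(seq, seq[1:]):
        h, s = _NN[a + b]
        dh += h
        ds += s
    for h, s in (_INIT[seq[0]], _INIT[seq[-1]]):
        dh += h
        ds += s
    return dh, ds


def duplex_tm(seq: str, params: ThermoParams = DEFAULT_PARAMS) -> float:
    """Two-state Tm (C) of *seq* paired with its perfect complement.

    Accepts any length >= 2; used internally on short stems as well as
    full-length oligos.  Salt correction: dS += 0.368 (N-1) ln[Na+].
    """
    seq = _validate(seq, min_len=2)
    dh, ds = _nn_sums(seq)
    ds += 0.368 * (len(seq) - 1) * math.log(params.monovalent_salt / 1000.0)
    c_t = params.oligo_conc * 1e-9
    denom = ds + R_GAS * math.log(c_t / 4.0)
    if denom >= 0:  # unphysical for a binding duplex; treat as no duplex
        return ABSOLUTE_ZERO_C
    return dh * 1000.0 / denom - T_KELVIN


def melting_temperature(seq: str, params: ThermoParams = DEFAULT_PARAMS) -> float:
    """Nearest-neighbor Tm of an oligo (length >= 8) with its complement."""
    return duplex_tm(_validate(seq, min_len=8), params)


def end_stability_dg(seq: str, params: ThermoParams = DEFAULT_PARAMS) -> float:
    """|dG| (kcal/mol) at the reference temperature of the 3'-terminal
    pentamer hybridized as a perfect duplex.

    A large value means a "sticky" 3' end prone to mispriming and
    spurious extension/ligation.
    """
    seq = _validate(seq, min_len=5)
    dh, ds = _nn_sums(seq[-5:])
    t_ref = params.temperature_ref + T_KELVIN
    return abs(dh - t_ref * ds / 1000.0)


def _stem_runs(seq: str, intramolecular: bool, min_loop: int = 3):
    """Yield maximal ungapped complementary stems as (start, length).

    Pairs position i of one strand with position j of the (same or a
    second) copy of *seq* read antiparallel; a pair is valid when
    seq[j] == complement(seq[i]).  For a fixed i+j the valid i form
    runs; each run is a candidate stem whose sequence is seq[a:b+1].

    intramolecular=True restricts to i < j with a loop of at least
    *min_loop* unpaired bases between the innermost pair (a hairpin);
    otherwise all offsets are allowed (a self-dimer).
    """
    n = len(seq)
    comp = seq.translate(_COMPLEMENT)
    for s in range(0, 2 * n - 1):
        lo = max(0, s - n + 1)
        hi = min(n - 1, s)
        if intramolecular:
            # innermost pair (i, s-i) needs s - 2i - 1 >= min_loop
            hi = min(hi, (s - min_loop - 1) // 2)
        a = None
        i = lo
        while i <= hi + 1:
            ok = i <= hi and comp[i] == seq[s - i]
            if ok and a is None:
                a = i
            elif not ok and a is not None:
                yield a, i - a
                a = None
            i += 1


def _best_stem_tm(
    seq: str,
    params: ThermoParams,
    intramolecular: bool,
    anchor_end: bool = False,
) -> float:
    """Max duplex Tm over all (sub-)stems; -273.15 if none of length >= 2.

    Tm is not monotone under stem extension (initiation terms change and
    weak stacks can dilute a strong core), so every contiguous sub-run of
    each maximal run is scored.  anchor_end requires the stem to pair the
    3'-terminal base of the molecule.
    """
    n = len(seq)
    best = ABSOLUTE_ZERO_C
    for a, length in _stem_runs(seq, intramolecular):
        b = a + length - 1
        for sub_a in range(a, b):
            for sub_b in range(sub_a + 1, b + 1):
                # A dimer stem and its mirror (the same duplex seen from the
                # second molecule) have equal Tm, so anchoring the 3' base is
                # equivalent to requiring the run to reach position n-1.
                if anchor_end and sub_b != n - 1:
                    continue
                tm = duplex_tm(seq[sub_a : sub_b + 1], params)
                if tm > best:
                    best = tm
    return best


def structure_report(seq: str, params: ThermoParams = DEFAULT_PARAMS) -> ThermoReport:
    """Full thermodynamic QC report for one oligo (length >= 8).

    hairpin_tm   : Tm of the strongest intramolecular foldback stem
                   (ungapped, loop >= 3).
    self_any_tm  : Tm of the strongest ungapped stem between two copies
                   of the oligo (self-dimer).
    self_end_tm  : as self_any_tm but the stem must pair the 3'-terminal
                   base, i.e. a self-dimer able to extend/ligate.
    end_stability_dg : |dG| of the 3' pentamer duplex at the reference
                   temperature.
    """
    seq = _validate(seq, min_len=8)
    return ThermoReport(
        tm=duplex_tm(seq, params),
        gc_percent=gc_percent(seq),
        hairpin_tm=_best_stem_tm(seq, params, intramolecular=True),
        self_any_tm=_best_stem_tm(seq, params, intramolecular=False),
        self_end_tm=_best_stem_tm(seq, params, intramolecular=False, anchor_end=True),
        end_stability_dg=end_stability_dg(seq, params),
    )
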