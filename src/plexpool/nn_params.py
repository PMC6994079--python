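"""Nearest-neighbour DNA duplex parameters (unified oligonucleotide set).

ΔH in kcal/mol and ΔS in cal/(mol·K) for dinucleotide steps, covering the ten
Watson–Crick stacks (SantaLucia's unified set) and the internal
single-mismatch stacks measured by Allawi & SantaLucia (G·T, G·A, C·T, A·C)
and Peyret et al. (A·A, C·C, G·G, T·T).

Key convention: ``"XY/WZ"`` is the duplex step 5'-XY-3' paired with
3'-WZ-5' (W under X, Z under Y).  Each physical step can be read from either
strand; :func:`lookup` tries the key as given and then the equivalent
other-strand reading 5'-ZW-3'/3'-YX-5'.

TABLE_VERSION identifies this parameter compilation.
"""

from __future__ import annotations

TABLE_VERSION = "unified-1998+mismatch-allawi-peyret/1"

# Watson-Crick stacks (unified set): (dH kcal/mol, dS cal/mol/K)
NN_WATSON_CRICK: dict[str, tuple[float, float]] = {
    "AA/TT": (-7.9, -22.2),
    "AT/TA": (-7.2, -20.4),
    "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7),
    "GT/CA": (-8.4, -22.4),
    "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2),
    "CG/GC": (-10.6, -27.2),
    "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}

# Internal single mismatches flanked by Watson-Crick pairs.
NN_INTERNAL_MISMATCH: dict[str, tuple[float, float]] = {
    # G.T mismatches
    "AG/TT": (1.0, 0.9),
    "AT/TG": (-2.5, -8.3),
    "CG/GT": (-4.1, -11.7),
    "CT/GG": (-2.8, -8.0),
    "GG/CT": (3.3, 10.4),
    "GG/TT": (5.8, 16.3),
    "GT/CG": (-4.4, -12.3),
    "GT/TG": (4.1, 9.5),
    "TG/AT": (-0.1, -1.7),
    "TG/GT": (-1.4, -6.2),
    "TT/AG": (-1.3, -5.3),
    # G.A mismatches
    "AA/TG": (-0.6, -2.3),
    "AG/TA": (-0.7, -2.3),
    "CA/GG": (-0.7, -2.3),
    "CG/GA": (-4.0, -13.2),
    "GA/CG": (-0.6, -1.0),
    "GG/CA": (0.5, 3.2),
    "TA/AG": (0.7, 0.7),
    "TG/AA": (3.0, 7.4),
    # C.T mismatches
    "AC/TT": (0.7, 0.2),
    "AT/TC": (-1.2, -6.2),
    "CC/GT": (-0.8, -4.5),
    "CT/GC": (-1.5, -6.1),
    "GC/CT": (2.3, 5.4),
    "GT/CC": (5.2, 13.5),
    "TC/AT": (1.2, 0.7),
    "TT/AC": (1.0, 0.7),
    # A.C mismatches
    "AA/TC": (2.3, 4.6),
    "AC/TA": (5.3, 14.6),
    "CA/GC": (1.9, 3.7),
    "CC/GA": (0.6, -0.6),
    "GA/CC": (5.2, 14.2),
    "GC/CA": (-0.7, -3.8),
    "TA/AC": (3.4, 8.0),
    "TC/AA": (7.6, 20.2),
    # A.A mismatches
    "AA/TA": (1.2, 1.7),
    "CA/GA": (-0.9, -4.2),
    "GA/CA": (-2.9, -9.8),
    "TA/AA": (4.7, 12.9),
    # C.C mismatches
    "AC/TC": (0.0, -4.4),
    "CC/GC": (-1.5, -7.2),
    "GC/CC": (3.6, 8.9),
    "TC/AC": (6.1, 16.4),
    # G.G mismatches
    "AG/TG": (-3.1, -9.5),
    "CG/GG": (-4.9, -15.3),
    "GG/CG": (-6.0, -15.8),
    "TG/AG": (1.6, 3.6),
    # T.T mismatches
    "AT/TT": (-2.7, -10.8),
    "CT/GT": (-5.0, -15.8),
    "GT/CT": (-2.2, -8.4),
    "TT/AT": (0.2, -1.5),
}

NN_ALL: dict[str, tuple[float, float]] = {**NN_WATSON_CRICK, **NN_INTERNAL_MISMATCH}


class MissingStepError(KeyError):
    """A dinucleotide step is absent from the parameter table."""


def lookup(top: str, bottom: str) -> tuple[float, float]:
    """(ΔH, ΔS) for the step 5'-top-3' / 3'-bottom-5'.

    ``top`` and ``bottom`` are two-base strings; ``bottom[k]`` is paired
    under ``top[k]``.  Falls back to the other-strand reading of the same
    physical step.  Raises MissingStepError for steps with two mismatched
    columns (not tabulated; the model never needs them).
    """
    key = f"{top}/{bottom}"
    hit = NN_ALL.get(key)
    if hit is None:
        hit = NN_ALL.get(f"{bottom[::-1]}/{top[::-1]}")
    if hit is None:
        raise MissingStepError(f"no nearest-neighbour parameters for step {key}")
    return hit
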