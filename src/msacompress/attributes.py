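"""Per-sequence physicochemical attributes and their distribution statistics.

For each protein sequence this module computes

* a sliding-window **hydrophobicity profile** and the **overall
  hydrophobicity index** (HI) — the mean scale value over the sequence,
  Kyte–Doolittle by default;
* the **theoretical isoelectric point** (pI) — the pH at which the
  Henderson–Hasselbalch net charge over ionizable side chains and termini
  crosses zero, located by bisection;

and, across a sequence set, the sample mean, standard deviation (n−1
denominator), skewness (third standardized central moment) and *excess*
kurtosis (normal distribution → 0) of each attribute.

Ambiguity codes (B/Z/X/U/O) carry no scale value and no charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .records import STANDARD_AA, SequenceSet

# Kyte & Doolittle hydropathy values (dimensionless).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Residue → scale value for all 20 standard residues."""

    values: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")

    @classmethod
    def kyte_doolittle(cls) -> "HydrophobicityScale":
        return cls(values=dict(KYTE_DOOLITTLE), name="Kyte-Doolittle")

    @classmethod
    def from_file(cls, path: str | Path) -> "HydrophobicityScale":
        """Two-column text: residue letter, value; '#' comments allowed."""
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                res, val = line.split()[:2]
                values[res.upper()] = float(val)
        return cls(values=values, name=Path(path).stem)


@dataclass(frozen=True)
class PKaTable:
    """pKa values for the ionizable groups entering the net-charge sum.

    ``acidic`` groups (side chains D, E, C, Y and the C-terminus) lose a
    proton with increasing pH and contribute negative charge; ``basic``
    groups (H, K, R side chains and the N-terminus) contribute positive
    charge.  Defaults are the EMBOSS values.
    """

    acidic: dict[str, float]
    basic: dict[str, float]
    n_term: float = 8.6
    c_term: float = 3.6
    name: str = "EMBOSS"

    def __post_init__(self) -> None:
        for pka in [*self.acidic.values(), *self.basic.values(), self.n_term, self.c_term]:
            if not 0 < pka < 14:
                raise ValueError(f"pKa {pka} outside (0, 14)")

    @classmethod
    def emboss(cls) -> "PKaTable":
        return cls(
            acidic={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
            basic={"H": 6.5, "K": 10.8, "R": 12.5},
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PKaTable":
        """Two-column text: group (residue letter, Nterm or Cterm), pKa."""
        tbl = cls.emboss()
        acidic, basic = dict(tbl.acidic), dict(tbl.basic)
        n_term, c_term = tbl.n_term, tbl.c_term
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, val = line.split()[:2]
                key = key.upper()
                if key == "NTERM":
                    n_term = float(val)
                elif key == "CTERM":
                    c_term = float(val)
                elif key in acidic:
                    acidic[key] = float(val)
                elif key in basic:
                    basic[key] = float(val)
                else:
                    raise ValueError(f"unknown ionizable group {key!r}")
        return cls(acidic=acidic, basic=basic, n_term=n_term, c_term=c_term,
                   name=Path(path).stem)


def hydrophobicity_profile(
    seq: str, scale: HydrophobicityScale | None = None, window: int = 9
) -> list[float]:
    """Sliding-window mean of scale values, centered windows only.

    Profile length is ``len(seq) - window + 1``; positions whose window
    extends past either end are omitted.  Residues without a scale value
    (ambiguity codes) are excluded from the window mean; a window with no
    scored residue yields NaN.
    """
    scale = scale or HydrophobicityScale.kyte_doolittle()
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    vals = [scale.values.get(c) for c in seq.upper()]
    profile: list[float] = []
    for i in range(len(seq) - window + 1):
        scored = [v for v in vals[i : i + window] if v is not None]
        profile.append(sum(scored) / len(scored) if scored else math.nan)
    return profile


def overall_hi(seq: str, scale: HydrophobicityScale | None = None) -> float:
    """Overall hydrophobicity index: mean scale value over scored residues."""
    scale = scale or HydrophobicityScale.kyte_doolittle()
    if not seq:
        raise ValueError("empty sequence")
    scored = [scale.values[c] for c in seq.upper() if c in scale.values]
    return sum(scored) / len(scored) if scored else math.nan


def net_charge(seq: str, ph: float, pka: PKaTable | None = None) -> float:
    """Henderson–Hasselbalch net charge of ``seq`` at a given pH."""
    pka = pka or PKaTable.emboss()
    seq = seq.upper()
    charge = 1.0 / (1.0 + 10 ** (ph - pka.n_term))
    charge -= 1.0 / (1.0 + 10 ** (pka.c_term - ph))
    for res, val in pka.basic.items():
        charge += seq.count(res) / (1.0 + 10 ** (ph - val))
    for res, val in pka.acidic.items():
        charge -= seq.count(res) / (1.0 + 10 ** (val - ph))
    return charge


def theoretical_pi(seq: str, pka: PKaTable | None = None, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique; with the
    termini always present it lies strictly inside (0, 14).
    """
    if not seq:
        raise ValueError("empty sequence")
    pka = pka or PKaTable.emboss()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def moment_stats(values) -> tuple[float, float, float, float]:
    """(mean, sample σ, skewness, excess kurtosis) of a list of scalars.

    σ needs ≥2 finite values, skewness/kurtosis ≥3; a constant sample has
    σ = 0 and NaN skewness/kurtosis (0/0).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return (math.nan,) * 4
    mean = float(x.mean())
    sigma = float(x.std(ddof=1)) if x.size >= 2 else math.nan
    if x.size >= 3 and x.std() > 0:
        skew = float(_st.skew(x, bias=True))
        kurt = float(_st.kurtosis(x, fisher=True, bias=True))
    else:
        skew = kurt = math.nan
    return mean, sigma, skew, kurt


def attribute_report(
    seqset: SequenceSet,
    scale: HydrophobicityScale | None = None,
    pka: PKaTable | None = None,
) -> pd.DataFrame:
    """Per-record HI and pI for a set; set-level moments in ``df.attrs``.

    The returned frame has columns ``accession, length, hi, pi``; the
    four-moment summary of each attribute is stored under
    ``df.attrs["moments"]`` as ``{attribute: (mean, sigma, skew, ex_kurtosis)}``.
    """
    scale = scale or HydrophobicityScale.kyte_doolittle()
    pka = pka or PKaTable.emboss()
    rows = [
        {
            "accession": rec.accession,
            "length": len(rec),
            "hi": overall_hi(rec.sequence, scale),
            "pi": theoretical_pi(rec.sequence, pka),
        }
        for rec in seqset
    ]
    df = pd.DataFrame(rows)
    df.attrs["moments"] = {
        attr: moment_stats(df[attr].to_numpy()) for attr in ("hi", "pi")
    }
    return df
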