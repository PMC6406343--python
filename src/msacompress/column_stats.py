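"""Per-column conservation statistics for a protein multiple alignment.

Two statistics are computed for every alignment column:

**Shannon information entropy**

.. math:: I_j = -\\sum_x p_{xj} \\log p_{xj}

where :math:`p_{xj}` is the frequency of residue type *x* in column *j*.
A fully conserved column scores 0; variability pushes the value up.  With
the logarithm taken to base 20 the entropy of a 20-letter residue column is
bounded by 1, reached at the uniform column, which puts entropy on the same
[0, 1] display scale as the diversity index below.

**Simpson population diversity index (PDI)** over physicochemical residue
classes

.. math:: \\mathrm{PDI} = 1 - \\sum_{i=1}^{k} \\frac{n_i (n_i - 1)}{N (N - 1)}

the probability that two residues drawn from the column without replacement
belong to *different* classes; :math:`n_i` is the count of residues in
class *i* and :math:`N` the column total.  A column whose residues all share
one physicochemical class scores 0 even if the residues differ, so PDI
measures chemical (rather than literal) conservation.

The default classification partitions the 20 standard residues into eight
types: hydrophobic (A, I, L, V), aromatic (F, Y, W), small (G), special
(C), hydrophilic (N, Q, S, T), negatively charged (D, E), positively
charged (R, K) and an eighth class gathering H, M and P. The scheme is
overridable from a plain-text config file.

Gap handling is a policy choice: by default gaps (and ambiguity codes,
which have no class) are excluded from the counts, shrinking *N*;
``gap_mode="as_symbol"`` instead treats ``-`` as a 21st residue symbol in
the entropy.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from Bio import AlignIO

from .records import GAP, STANDARD_AA

GapMode = Literal["exclude", "as_symbol"]
LogBase = Literal["natural", "20"]

DEFAULT_CLASSES: tuple[tuple[str, str], ...] = (
    ("hydrophobic", "AILV"),
    ("aromatic", "FYW"),
    ("small", "G"),
    ("special", "C"),
    ("hydrophilic", "NQST"),
    ("negative", "DE"),
    ("positive", "RK"),
    ("other", "HMP"),
)


@dataclass(frozen=True)
class ResidueClassScheme:
    """Disjoint partition of the 20 standard residues into named classes."""

    classes: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        union: set[str] = set()
        for name, residues in self.classes:
            if union & residues:
                raise ValueError(f"class {name!r} overlaps an earlier class")
            union |= residues
        if union != set(STANDARD_AA):
            raise ValueError(
                f"classes must cover exactly the 20 standard residues; "
                f"missing {sorted(set(STANDARD_AA) - union)}, "
                f"extra {sorted(union - set(STANDARD_AA))}"
            )
        object.__setattr__(
            self,
            "_class_of",
            {res: i for i, (_, residues) in enumerate(self.classes) for res in residues},
        )

    @property
    def k(self) -> int:
        return len(self.classes)

    def class_index(self, residue: str) -> int | None:
        """Index of the class containing ``residue``; None for gap/ambiguity."""
        return self._class_of.get(residue)  # type: ignore[attr-defined]

    @classmethod
    def default(cls) -> "ResidueClassScheme":
        return cls(tuple((n, frozenset(r)) for n, r in DEFAULT_CLASSES))

    @classmethod
    def from_file(cls, path: str | Path) -> "ResidueClassScheme":
        """Lines of ``classname: residue letters``; '#' comments allowed."""
        classes = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                name, _, residues = line.partition(":")
                classes.append((name.strip(), frozenset(residues.strip().upper())))
        return cls(tuple(classes))

    @classmethod
    def merged(cls, scheme: "ResidueClassScheme", i: int, j: int) -> "ResidueClassScheme":
        """Coarser scheme with classes ``i`` and ``j`` merged (for refinement tests)."""
        if i == j:
            return scheme
        i, j = sorted((i, j))
        classes = list(scheme.classes)
        name_i, res_i = classes[i]
        name_j, res_j = classes.pop(j)
        classes[i] = (f"{name_i}+{name_j}", res_i | res_j)
        return cls(tuple(classes))


@dataclass
class Alignment:
    """Equal-length aligned sequences for one orthologue group."""

    rows: list[tuple[str, str]]  # (accession, aligned sequence)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        L = len(self.rows[0][1])
        if L < 1:
            raise ValueError("alignment length must be >= 1")
        for acc, seq in self.rows:
            if len(seq) != L:
                raise ValueError(f"row {acc!r} has length {len(seq)}, expected {L}")
        self.rows = [(acc, seq.upper()) for acc, seq in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.rows)

    def row(self, accession: str) -> str:
        for acc, seq in self.rows:
            if acc == accession:
                return seq
        raise KeyError(accession)

    @classmethod
    def read(cls, path: str | Path, fmt: str | None = None) -> "Alignment":
        """Read an aligned FASTA or Clustal file (format sniffed by suffix)."""
        path = Path(path)
        if fmt is None:
            fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls([(rec.id, str(rec.seq)) for rec in aln])

    def write(self, path: str | Path, fmt: str = "fasta") -> None:
        with open(path, "w") as fh:
            if fmt == "fasta":
                for acc, seq in self.rows:
                    fh.write(f">{acc}\n{seq}\n")
            else:
                raise ValueError(f"unsupported write format {fmt!r}")


def _column_counts(column: str, gap_mode: GapMode) -> Counter:
    """Symbol counts entering the entropy for one column string."""
    counts: Counter = Counter()
    for c in column.upper():
        if c in STANDARD_AA:
            counts[c] += 1
        elif c == GAP and gap_mode == "as_symbol":
            counts[GAP] += 1
        # ambiguity codes and (in exclude mode) gaps are dropped
    return counts


def column_entropy(
    column: str, log_base: LogBase = "20", gap_mode: GapMode = "exclude"
) -> float:
    """Shannon entropy of one column string; NaN if no symbol is counted.

    ``column`` is the vertical slice of the alignment, e.g. ``"AAVF-"``.
    Conserved column → 0.0; base-20 entropy of a gap-free column ≤ 1.
    """
    counts = _column_counts(column, gap_mode)
    n = sum(counts.values())
    if n == 0:
        return math.nan
    log = math.log if log_base == "natural" else lambda v: math.log(v) / math.log(20.0)
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * log(p)  # 0·log 0 never arises: counts are positive
    return h


def column_pdi(column: str, scheme: ResidueClassScheme | None = None) -> float:
    """Simpson diversity of one column over residue classes; NaN if N < 2.

    Gaps and ambiguity codes have no class and never enter the counts.
    """
    scheme = scheme or ResidueClassScheme.default()
    class_counts: Counter = Counter()
    for c in column.upper():
        idx = scheme.class_index(c)
        if idx is not None:
            class_counts[idx] += 1
    N = sum(class_counts.values())
    if N < 2:
        return math.nan
    same = sum(n * (n - 1) for n in class_counts.values())
    return 1.0 - same / (N * (N - 1))


@dataclass
class ConservationProfile:
    """Per-column entropy, PDI and gap fraction for one alignment."""

    entropy: list[float]
    pdi: list[float]
    gap_fraction: list[float]
    n_effective: list[int]
    log_base: LogBase = "20"
    gap_mode: GapMode = "exclude"
    group_id: str = ""
    scheme: ResidueClassScheme = field(default_factory=ResidueClassScheme.default)

    def __len__(self) -> int:
        return len(self.entropy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": range(1, len(self) + 1),
                "entropy": self.entropy,
                "pdi": self.pdi,
                "gap_fraction": self.gap_fraction,
                "n_effective": self.n_effective,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservationProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            entropy=df["entropy"].tolist(),
            pdi=df["pdi"].tolist(),
            gap_fraction=df["gap_fraction"].tolist(),
            n_effective=df["n_effective"].astype(int).tolist(),
        )


def profile(
    aln: Alignment,
    scheme: ResidueClassScheme | None = None,
    log_base: LogBase = "20",
    gap_mode: GapMode = "exclude",
    group_id: str = "",
) -> ConservationProfile:
    """Column-wise conservation profile of a whole alignment.

    Gap fraction is recorded per column regardless of ``gap_mode``.
    """
    scheme = scheme or ResidueClassScheme.default()
    entropy, pdi, gapf, neff = [], [], [], []
    for j in range(aln.length):
        col = aln.column(j)
        entropy.append(column_entropy(col, log_base, gap_mode))
        pdi.append(column_pdi(col, scheme))
        gapf.append(col.count(GAP) / len(col))
        neff.append(sum(_column_counts(col, gap_mode).values()))
    return ConservationProfile(
        entropy=entropy,
        pdi=pdi,
        gap_fraction=gapf,
        n_effective=neff,
        log_base=log_base,
        gap_mode=gap_mode,
        group_id=group_id,
        scheme=scheme,
    )
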