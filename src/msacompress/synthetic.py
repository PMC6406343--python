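"""Synthetic multigene-family generator.

Produces a paralogue template plus per-group orthologue MSAs with controlled
per-position residue distributions, so the whole pipeline can be exercised
and calibrated without any sequence download.  Each position of each group
is governed by a categorical residue distribution; the one-parameter default
puts probability *c* (the conservation level) on a designated consensus
residue and spreads ``(1 - c)/19`` over the remaining 19 residues, which has
a closed-form entropy and class-diversity — convenient ground truth for
parameter-recovery studies.

Columns are sampled i.i.d. across sequences and positions; gaps are placed
i.i.d. at a per-position rate.  There is no phylogeny and no substitution
model: the generator emulates column-wise conservation structure, not
evolutionary correlation between sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .column_stats import Alignment, ResidueClassScheme
from .heatmap import TemplateMatrix
from .records import GAP

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # canonical residue order for distributions


def conservation_distribution(c: float, consensus: str) -> dict[str, float]:
    """Categorical residue distribution with probability ``c`` on the consensus."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("conservation level must be in [0, 1]")
    if consensus not in AA_ORDER:
        raise ValueError(f"consensus {consensus!r} is not a standard residue")
    rest = (1.0 - c) / 19.0
    return {aa: (c if aa == consensus else rest) for aa in AA_ORDER}


def distribution_entropy(dist: dict[str, float], log_base: str = "20") -> float:
    """Population Shannon entropy of a residue distribution."""
    log_den = 1.0 if log_base == "natural" else math.log(20.0)
    return -sum(p * math.log(p) / log_den for p in dist.values() if p > 0)


def distribution_pdi(
    dist: dict[str, float], scheme: ResidueClassScheme | None = None
) -> float:
    """Population Simpson diversity of a distribution over residue classes."""
    scheme = scheme or ResidueClassScheme.default()
    class_p = [0.0] * scheme.k
    for aa, p in dist.items():
        idx = scheme.class_index(aa)
        if idx is not None:
            class_p[idx] += p
    return 1.0 - sum(p * p for p in class_p)


@dataclass
class FamilySpec:
    """Specification of a synthetic multigene family.

    ``conservation`` may be a scalar (all groups, all positions), a list of
    per-position levels (all groups), or a per-group mapping of such lists.
    Explicit per-position categorical distributions can be supplied through
    ``distributions`` (group → list of residue→probability maps), which
    overrides ``conservation`` for those groups.
    """

    n_groups: int = 3
    n_positions: int = 40
    n_sequences: int = 100
    conservation: float | list[float] | dict[str, list[float]] = 0.8
    distributions: dict[str, list[dict[str, float]]] = field(default_factory=dict)
    gap_rate: float = 0.0
    seed: int = 0
    include_reference: bool = True

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_positions < 1:
            raise ValueError("need at least one group and one position")
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence per group")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FamilySpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def group_ids(self) -> list[str]:
        explicit = list(self.distributions)
        generated = [f"grp{i + 1}" for i in range(self.n_groups - len(explicit))]
        return explicit + generated


@dataclass
class SyntheticFamily:
    """Generated template + per-group MSAs with their generating truth."""

    template: TemplateMatrix
    alignments: dict[str, Alignment]
    truth_entropy: dict[str, list[float]]  # base-20, per position
    truth_pdi: dict[str, list[float]]
    distributions: dict[str, list[dict[str, float]]]

    def write(self, outdir: str | Path) -> None:
        """Write template.fasta, groups.tsv and one aligned FASTA per group."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.template.template_aln.write(outdir / "template.fasta")
        with open(outdir / "groups.tsv", "w") as fh:
            fh.write("group_id\taccession\n")
            for gid, acc in zip(self.template.group_ids, self.template.accessions):
                fh.write(f"{gid}\t{acc}\n")
        for gid, aln in self.alignments.items():
            aln.write(outdir / f"{gid}.fasta")


def _group_distributions(
    spec: FamilySpec, gid: str, rng: np.random.Generator
) -> list[dict[str, float]]:
    if gid in spec.distributions:
        dists = []
        for d in spec.distributions[gid]:
            total = sum(d.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"group {gid!r}: distribution sums to {total}")
            dists.append(dict(d))
        if len(dists) != spec.n_positions:
            raise ValueError(
                f"group {gid!r}: {len(dists)} distributions for "
                f"{spec.n_positions} positions"
            )
        return dists
    if isinstance(spec.conservation, dict):
        levels = spec.conservation[gid]
    elif isinstance(spec.conservation, (int, float)):
        levels = [float(spec.conservation)] * spec.n_positions
    else:
        levels = list(spec.conservation)
    if len(levels) != spec.n_positions:
        raise ValueError(f"{len(levels)} conservation levels for {spec.n_positions} positions")
    consensus = rng.choice(list(AA_ORDER), size=spec.n_positions)
    return [conservation_distribution(c, aa) for c, aa in zip(levels, consensus)]


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Sample a synthetic family; reproducible under a fixed seed.

    Each group MSA contains its reference row (the per-position consensus,
    accession ``<group>_ref``) followed by ``n_sequences`` sampled rows.
    Returns the family together with the per-position population entropy
    (base 20) and PDI of the generating distributions.
    """
    rng = np.random.default_rng(spec.seed)
    group_ids = spec.group_ids()
    template_rows: list[tuple[str, str]] = []
    accessions: list[str] = []
    alignments: dict[str, Alignment] = {}
    truth_h: dict[str, list[float]] = {}
    truth_d: dict[str, list[float]] = {}
    all_dists: dict[str, list[dict[str, float]]] = {}

    for gid in group_ids:
        dists = _group_distributions(spec, gid, rng)
        all_dists[gid] = dists
        truth_h[gid] = [distribution_entropy(d) for d in dists]
        truth_d[gid] = [distribution_pdi(d) for d in dists]
        consensus = "".join(max(d, key=d.get) for d in dists)
        ref_acc = f"{gid}_ref"
        template_rows.append((ref_acc, consensus))
        accessions.append(ref_acc)

        # sample the residue matrix column by column
        cols = []
        for d in dists:
            aas = list(d)
            probs = np.array([d[a] for a in aas])
            cols.append(rng.choice(aas, size=spec.n_sequences, p=probs / probs.sum()))
        matrix = np.stack(cols, axis=1)  # (n_sequences, n_positions)
        if spec.gap_rate > 0:
            gaps = rng.random(matrix.shape) < spec.gap_rate
            matrix = np.where(gaps, GAP, matrix)
        rows = []
        if spec.include_reference:
            rows.append((ref_acc, consensus))
        for i in range(spec.n_sequences):
            rows.append((f"{gid}_s{i + 1}", "".join(matrix[i])))
        alignments[gid] = Alignment(rows)

    template = TemplateMatrix(Alignment(template_rows), group_ids, accessions)
    return SyntheticFamily(template, alignments, truth_h, truth_d, all_dists)
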