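"""Heat-map assembly: overlay per-group conservation profiles onto a
reference template alignment of paralogues.

The template is an alignment of the family's reference members (one row per
orthologue group, e.g. the human paralogues); its positions index the
heat-map rows, the groups index the columns.  Each group's per-column
statistic values are transferred from the group MSA to template coordinates
through the group's reference sequence, which must be present as a row of
the group MSA: the k-th ungapped residue of the group's template row
corresponds to the group-MSA column holding the k-th ungapped residue of
the reference row.  Template positions where the group's template row is
gapped carry no value.

Cells are colored on a [0, 1] scale — PDI natively, entropy via the base-20
logarithm: below 0.25 white (conserved), from 0.25 a linear green→red
gradient up to 1, missing cells grey (distinct from white, which means
conserved, not absent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .column_stats import Alignment, ConservationProfile
from .records import GAP

WHITE = (255, 255, 255)
GREEN = (0, 176, 80)
RED = (255, 0, 0)
GREY = (128, 128, 128)
COLOR_THRESHOLD = 0.25


@dataclass
class TemplateMatrix:
    """Reference paralogue alignment with group labels.

    ``group_ids[i]`` labels row *i* of ``template_aln``; ``accessions[i]``
    names the reference sequence that represents the group inside its own
    orthologue MSA.
    """

    template_aln: Alignment
    group_ids: list[str]
    accessions: list[str]

    def __post_init__(self) -> None:
        n = self.template_aln.n_rows
        if len(self.group_ids) != n or len(self.accessions) != n:
            raise ValueError("group_ids/accessions must match template row count")
        if len(set(self.group_ids)) != n:
            raise ValueError("group_ids must be unique")

    @property
    def n_positions(self) -> int:
        return self.template_aln.length

    def template_row(self, group_id: str) -> str:
        i = self.group_ids.index(group_id)
        return self.template_aln.rows[i][1]

    def reference_accession(self, group_id: str) -> str:
        return self.accessions[self.group_ids.index(group_id)]

    @classmethod
    def read(cls, template_path: str | Path, groups_path: str | Path) -> "TemplateMatrix":
        """Template from aligned FASTA plus a two-column group mapping TSV.

        The mapping file has columns ``group_id`` and ``accession``; rows of
        the template FASTA are matched to groups by accession (header id).
        """
        aln = Alignment.read(template_path)
        groups = pd.read_csv(groups_path, sep="\t")
        if not {"group_id", "accession"} <= set(groups.columns):
            raise ValueError("groups file needs columns: group_id, accession")
        by_acc = {acc: seq for acc, seq in aln.rows}
        rows, ids, accs = [], [], []
        for _, rec in groups.iterrows():
            acc = str(rec["accession"])
            if acc not in by_acc:
                raise ValueError(f"template alignment has no row {acc!r}")
            rows.append((acc, by_acc[acc]))
            ids.append(str(rec["group_id"]))
            accs.append(acc)
        return cls(Alignment(rows), ids, accs)


def map_profile_to_template(
    prof: ConservationProfile,
    group_id: str,
    tpl: TemplateMatrix,
    group_aln: Alignment,
    statistic: str = "entropy",
) -> list[float]:
    """Transfer one group's per-column values to template positions.

    Returns a list of length ``tpl.n_positions``; template positions where
    the group's template row is gapped are NaN.
    """
    values = getattr(prof, statistic)
    template_row = tpl.template_row(group_id)
    ref_acc = tpl.reference_accession(group_id)
    try:
        ref_row = group_aln.row(ref_acc)
    except KeyError:
        raise ValueError(
            f"group {group_id!r}: reference sequence {ref_acc!r} "
            f"not found in the group MSA"
        ) from None

    # group-MSA column index of each ungapped reference residue, in order
    ref_columns = [j for j, c in enumerate(ref_row) if c != GAP]
    n_template_res = sum(1 for c in template_row if c != GAP)
    if n_template_res != len(ref_columns):
        raise ValueError(
            f"group {group_id!r}: template row has {n_template_res} residues "
            f"but reference row in the group MSA has {len(ref_columns)}"
        )

    out = [math.nan] * len(template_row)
    k = 0
    for t, c in enumerate(template_row):
        if c != GAP:
            out[t] = values[ref_columns[k]]
            k += 1
    return out


@dataclass
class HeatMapGrid:
    """Template-position × group matrix of statistic values."""

    values: np.ndarray  # (n_positions, n_groups), NaN = missing
    group_ids: list[str]
    statistic: str = "entropy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.group_ids):
            raise ValueError("values must be (n_positions, n_groups)")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.group_ids)
        df.insert(0, "position", range(1, self.n_positions + 1))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path, statistic: str = "entropy") -> "HeatMapGrid":
        df = pd.read_csv(path, sep="\t")
        groups = [c for c in df.columns if c != "position"]
        return cls(df[groups].to_numpy(dtype=float), groups, statistic)


def build_grid(
    tpl: TemplateMatrix,
    profiles: dict[str, ConservationProfile],
    alignments: dict[str, Alignment],
    statistic: str = "entropy",
) -> HeatMapGrid:
    """Assemble the heat-map grid from per-group profiles and MSAs.

    Every group of the template must have a profile and an alignment.
    """
    missing = [g for g in tpl.group_ids if g not in profiles or g not in alignments]
    if missing:
        raise ValueError(f"no profile/alignment for group(s): {', '.join(missing)}")
    cols = [
        map_profile_to_template(profiles[g], g, tpl, alignments[g], statistic)
        for g in tpl.group_ids
    ]
    return HeatMapGrid(np.array(cols, dtype=float).T, list(tpl.group_ids), statistic)


def colorize(value: float) -> tuple[int, int, int]:
    """Map a normalized [0, 1] statistic value to an RGB color.

    Below 0.25 → white; 0.25 → green, rising linearly to red at 1.0 (values
    above 1 clip to red); NaN (missing) → grey.  Negative values violate the
    entropy/PDI contracts and raise.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return GREY
    if value < 0:
        raise ValueError(f"statistic value {value} is negative")
    if value < COLOR_THRESHOLD:
        return WHITE
    t = min((value - COLOR_THRESHOLD) / (1.0 - COLOR_THRESHOLD), 1.0)
    return tuple(round(g + t * (r - g)) for g, r in zip(GREEN, RED))  # type: ignore[return-value]


def colorize_grid(grid: HeatMapGrid) -> np.ndarray:
    """(n_positions, n_groups, 3) uint8 RGB image of the grid."""
    img = np.empty((*grid.values.shape, 3), dtype=np.uint8)
    for i in range(grid.values.shape[0]):
        for j in range(grid.values.shape[1]):
            img[i, j] = colorize(grid.values[i, j])
    return img


def render(grid: HeatMapGrid, out: str | Path, fmt: str | None = None) -> Path:
    """Write the grid as tsv (raw values), png/svg (colorized) or xlsx.

    Format is taken from the filename suffix unless given explicitly.
    """
    out = Path(out)
    fmt = (fmt or out.suffix.lstrip(".")).lower()
    if fmt == "tsv":
        grid.to_tsv(out)
    elif fmt in {"png", "svg"}:
        _render_image(grid, out)
    elif fmt == "xlsx":
        _render_xlsx(grid, out)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    return out


def _render_image(grid: HeatMapGrid, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = colorize_grid(grid)
    n_pos, n_grp = grid.values.shape
    fig, ax = plt.subplots(
        figsize=(max(2.0, 0.4 * n_grp + 1.2), max(2.0, 0.12 * n_pos + 1.0))
    )
    ax.imshow(img, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(n_grp), grid.group_ids, rotation=90, fontsize=7)
    ax.xaxis.tick_top()
    step = max(1, n_pos // 40)
    ax.set_yticks(range(0, n_pos, step), [str(i + 1) for i in range(0, n_pos, step)],
                  fontsize=7)
    ax.set_ylabel("template position")
    ax.set_title(grid.statistic, pad=28)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def _render_xlsx(grid: HeatMapGrid, out: Path) -> None:
    from openpyxl import Workbook
    from openpyxl.styles import PatternFill

    wb = Workbook()
    ws = wb.active
    ws.title = grid.statistic
    ws.append(["position", *grid.group_ids])
    for i in range(grid.n_positions):
        row = [i + 1]
        for v in grid.values[i]:
            row.append(None if math.isnan(v) else round(float(v), 6))
        ws.append(row)
        for j, v in enumerate(grid.values[i]):
            rgb = colorize(v)
            hexcolor = "%02X%02X%02X" % rgb
            ws.cell(row=i + 2, column=j + 2).fill = PatternFill(
                start_color=hexcolor, end_color=hexcolor, fill_type="solid"
            )
    wb.save(out)
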