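"""Codon translation, color palettes, logo layout and figure rendering.

Each codon glyph is drawn as the 3-letter codon text stretched to fill
its box, colored by a property class of the encoded amino acid. An
ambiguous codon that still resolves to a single amino acid (e.g. GCN,
always Ala) is colored like that amino acid; one compatible with several
amino acids gets the dedicated ambiguous color.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .codon_matrix import BitMatrix, ProbabilityMatrix
from .errors import AlphabetError, ConfigError

#: Expansion of every IUPAC nucleotide code to the unambiguous bases it covers.
IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Symbol returned for translated stop codons.
STOP = "*"

#: Symbol returned when an ambiguous codon maps to several amino acids.
AMBIGUOUS = "X"

_TABLE1 = unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """Translate under the standard genetic code (table 1).

    Returns a one-letter amino acid, ``"*"`` for stop, or ``"X"`` when
    ambiguity codes leave more than one possible amino acid.
    """
    if len(codon) != 3 or any(c not in IUPAC_EXPANSION for c in codon):
        raise AlphabetError(f"malformed codon {codon!r}")
    amino_acids = {
        STOP if expanded in _TABLE1.stop_codons
        else _TABLE1.forward_table[expanded]
        for expanded in (
            a + b + c
            for a in IUPAC_EXPANSION[codon[0]]
            for b in IUPAC_EXPANSION[codon[1]]
            for c in IUPAC_EXPANSION[codon[2]]
        )
    }
    if len(amino_acids) == 1:
        return amino_acids.pop()
    return AMBIGUOUS


@dataclass(frozen=True)
class Palette:
    """Amino-acid class coloring for codon glyphs."""

    name: str
    mapping: dict[str, str]  # one-letter aa -> color
    stop_color: str = "darkred"
    ambiguous_color: str = "gray"

    def color_for(self, symbol: str) -> str:
        if symbol == STOP:
            return self.stop_color
        if symbol == AMBIGUOUS:
            return self.ambiguous_color
        try:
            return self.mapping[symbol]
        except KeyError:
            raise AlphabetError(f"unknown amino acid symbol {symbol!r}")


def _classes(**groups: str) -> dict[str, str]:
    return {aa: color for color, members in groups.items() for aa in members}


# Chemistry-style classes (also WebLogo's default protein scheme):
# polar green, neutral purple, basic blue, acidic red, hydrophobic black.
_CHEMISTRY = _classes(
    green="GSTYC", purple="QN", blue="KRH", red="DE", black="AVLIPWFM"
)

PALETTES: dict[str, Palette] = {
    "weblogo_protein": Palette("weblogo_protein", dict(_CHEMISTRY)),
    "chemistry": Palette("chemistry", dict(_CHEMISTRY)),
    "hydrophobicity": Palette(
        "hydrophobicity",
        _classes(blue="RKDENQ", green="SGHTAP", black="YVMCLFIW"),
    ),
    # only K/R/H and D/E carry charge; everything else is neutral gray
    "charge": Palette(
        "charge", _classes(blue="KRH", red="DE", gray="ACFGILMNPQSTVWY")
    ),
}


def get_palette(name: str) -> Palette:
    try:
        return PALETTES[name]
    except KeyError:
        raise ConfigError(
            f"unknown palette {name!r}; choices: {sorted(PALETTES)}"
        )


def assign_color(codon: str, palette: Palette) -> str:
    """Color for a codon glyph: palette class of its translation."""
    return palette.color_for(translate_codon(codon))


@dataclass(frozen=True)
class GlyphBox:
    """One codon glyph: its position, vertical extent and color."""

    codon: str
    position: int  # 1-based codon position
    y_bottom: float
    y_top: float
    color: str

    @property
    def height(self) -> float:
        return self.y_top - self.y_bottom


@dataclass
class LogoLayout:
    """Geometry of the whole logo, independent of any drawing backend."""

    boxes: list[GlyphBox]
    y_axis_max: float
    x_positions: int
    y_label: str

    def boxes_at(self, position: int) -> list[GlyphBox]:
        return [b for b in self.boxes if b.position == position]

    def to_json(self) -> str:
        return json.dumps(
            {
                "y_axis_max": self.y_axis_max,
                "x_positions": self.x_positions,
                "y_label": self.y_label,
                "boxes": [
                    {
                        "codon": b.codon,
                        "position": b.position,
                        "y_bottom": b.y_bottom,
                        "y_top": b.y_top,
                        "color": b.color,
                    }
                    for b in self.boxes
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class RenderSpec:
    """Figure-level options."""

    title: str = ""
    format: str = "png"
    dpi: int = 300
    y_mode: str = "bits"

    def __post_init__(self) -> None:
        if self.format not in ("png", "pdf"):
            raise ConfigError(
                f"unsupported format {self.format!r}; choices: png, pdf"
            )
        if self.dpi < 72:
            raise ConfigError(f"dpi must be >= 72, got {self.dpi}")
        if self.y_mode not in ("bits", "probability"):
            raise ConfigError(f"unknown y_mode {self.y_mode!r}")


def layout_logo(
    matrix: Union[BitMatrix, ProbabilityMatrix], palette: Palette
) -> LogoLayout:
    """Stack positive-valued codons bottom-up in ascending value order.

    The largest codon ends up on top; box extents are cumulative sums,
    so the stack total equals the matrix row sum.
    """
    if isinstance(matrix, BitMatrix):
        y_axis_max, y_label = matrix.smax, "bits"
    else:
        y_axis_max, y_label = 1.0, "probability"
    boxes: list[GlyphBox] = []
    for i, position in enumerate(matrix.positions):
        entries = [
            (matrix.codons[j], float(v))
            for j, v in enumerate(matrix.values[i])
            if v > 0
        ]
        # ascending height; ties broken lexicographically for determinism
        entries.sort(key=lambda e: (e[1], e[0]))
        y = 0.0
        for codon, value in entries:
            boxes.append(
                GlyphBox(
                    codon=codon,
                    position=position,
                    y_bottom=y,
                    y_top=y + value,
                    color=assign_color(codon, palette),
                )
            )
            y += value
    return LogoLayout(
        boxes=boxes,
        y_axis_max=y_axis_max,
        x_positions=len(matrix.positions),
        y_label=y_label,
    )


_GLYPH_FONT = FontProperties(family="monospace", weight="bold")


def _draw_glyph(ax, box: GlyphBox, pad: float = 0.05) -> None:
    """Stretch the codon text to fill the box via an affine transform."""
    tp = TextPath((0, 0), box.codon, size=1.0, prop=_GLYPH_FONT)
    bb = tp.get_extents()
    if bb.width == 0 or bb.height == 0:  # pragma: no cover
        return
    x0 = box.position - 0.5 + pad
    width = 1.0 - 2 * pad
    transform = (
        Affine2D()
        .translate(-bb.x0, -bb.y0)
        .scale(width / bb.width, box.height / bb.height)
        .translate(x0, box.y_bottom)
    )
    ax.add_patch(
        PathPatch(
            transform.transform_path(tp),
            facecolor=box.color,
            edgecolor="none",
        )
    )


def render(
    layout: LogoLayout, spec: RenderSpec, path: Union[str, Path]
) -> Path:
    """Render the layout to a PNG or PDF file."""
    path = Path(path)
    n = max(layout.x_positions, 1)
    fig, ax = plt.subplots(figsize=(max(0.6 * n, 3.0), 3.0))
    try:
        for box in layout.boxes:
            _draw_glyph(ax, box)
        ax.set_xlim(0.5, n + 0.5)
        ax.set_ylim(0, layout.y_axis_max if layout.y_axis_max > 0 else 1.0)
        ax.set_xticks(range(1, n + 1))
        ax.set_xlabel("codon position")
        ax.set_ylabel(layout.y_label)
        if spec.title:
            ax.set_title(spec.title)
        ax.spines["top"].set_visible(False)
        ax.spines["right"].set_visible(False)
        fig.tight_layout()
        fig.savefig(path, format=spec.format, dpi=spec.dpi)
    finally:
        plt.close(fig)
    return path
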