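"""SVG diagrams of repeat architectures.

One row per allele: numbered colour blocks left-to-right in repeat
order, filled from the variant palette; disrupted repeats (stop codon
or frameshift) are drawn black; partial repeats get a hatched outline.
Contiguous repeats share a baseline, interrupted at scaffold breaks.
Variant numbers are drawn in black or white by a relative-luminance
rule so they stay legible on any palette colour.  Output is plain
SVG 1.1 text and is byte-identical for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

from .alleles import AllelePanel  # noqa: F401  (re-export convenience)
from .catalog import RepeatArchitecture
from .palette import PaletteAssignment, _gamma_inv

__all__ = ["DiagramSpec", "render_diagram", "relative_luminance", "label_color"]

DISRUPTED_FILL = "#000000"


def relative_luminance(hexcode: str) -> float:
    """WCAG relative luminance of an sRGB hex colour."""
    r, g, b = (int(hexcode[i : i + 2], 16) / 255.0 for i in (1, 3, 5))
    rl, gl, bl = _gamma_inv(r), _gamma_inv(g), _gamma_inv(b)
    return 0.2126 * rl + 0.7152 * gl + 0.0722 * bl


def label_color(fill_hex: str) -> str:
    """White labels on dark fills, black on light; flips at 0.5."""
    return "#FFFFFF" if relative_luminance(fill_hex) < 0.5 else "#000000"


@dataclass
class DiagramSpec:
    rows: list[tuple[str, RepeatArchitecture]]
    palette: PaletteAssignment
    block_width: float = 34.0
    block_height: float = 24.0
    block_gap: float = 4.0
    row_gap: float = 18.0
    label_width: float = 120.0
    show_numbers: bool = True
    show_flags: bool = True
    highlights: list[tuple[int, int]] = field(default_factory=list)  # (row, ordinal)

    def validate(self) -> None:
        for label, arch in self.rows:
            for vid, flags in arch.repeats:
                disrupted = flags & {"has_stop", "frameshift_suspect"}
                if not disrupted and "partial" not in flags and vid not in self.palette.colors:
                    raise ValueError(
                        f"no palette colour for variant {vid} in row {label!r}"
                    )


def _block_fill(vid: int, flags: frozenset, palette: PaletteAssignment) -> str | None:
    if flags & {"has_stop", "frameshift_suspect"}:
        return DISRUPTED_FILL
    if "partial" in flags:
        return None  # hatched outline
    return palette.hex_of(vid)


def render_diagram(spec: DiagramSpec) -> str:
    """Render the diagram; returns the SVG document as a string."""
    spec.validate()
    bw, bh, gap = spec.block_width, spec.block_height, spec.block_gap
    n_cols = max((arch.n_repeats for _, arch in spec.rows), default=0)
    width = spec.label_width + n_cols * (bw + gap) + 20
    height = len(spec.rows) * (bh + spec.row_gap) + 20

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": f"{width:g}",
            "height": f"{height:g}",
            "font-family": "sans-serif",
        },
    )
    defs = ET.SubElement(svg, "defs")
    pattern = ET.SubElement(
        defs,
        "pattern",
        {
            "id": "hatch",
            "width": "6",
            "height": "6",
            "patternUnits": "userSpaceOnUse",
            "patternTransform": "rotate(45)",
        },
    )
    ET.SubElement(
        pattern,
        "line",
        {"x1": "0", "y1": "0", "x2": "0", "y2": "6", "stroke": "#888888",
         "stroke-width": "2"},
    )

    for r, (label, arch) in enumerate(spec.rows):
        y = 10 + r * (bh + spec.row_gap)
        ET.SubElement(
            svg,
            "text",
            {"x": "10", "y": f"{y + bh / 2 + 4:g}", "font-size": "13"},
        ).text = label
        breaks = set(arch.scaffold_breaks)
        for c, (vid, flags) in enumerate(arch.repeats):
            x = spec.label_width + c * (bw + gap)
            # baseline connector to the next block, unless a scaffold
            # break separates them
            if c + 1 < arch.n_repeats and (c + 1) not in breaks:
                ET.SubElement(
                    svg,
                    "line",
                    {
                        "x1": f"{x + bw:g}",
                        "y1": f"{y + bh / 2:g}",
                        "x2": f"{x + bw + gap:g}",
                        "y2": f"{y + bh / 2:g}",
                        "stroke": "#000000",
                        "stroke-width": "2",
                    },
                )
            fill = _block_fill(vid, flags, spec.palette)
            rect_attrs = {
                "x": f"{x:g}",
                "y": f"{y:g}",
                "width": f"{bw:g}",
                "height": f"{bh:g}",
                "stroke": "#333333",
                "stroke-width": "1",
            }
            rect_attrs["fill"] = fill if fill is not None else "url(#hatch)"
            ET.SubElement(svg, "rect", rect_attrs)
            if spec.show_numbers:
                text_fill = label_color(fill) if fill is not None else "#000000"
                ET.SubElement(
                    svg,
                    "text",
                    {
                        "x": f"{x + bw / 2:g}",
                        "y": f"{y + bh / 2 + 4:g}",
                        "font-size": "12",
                        "text-anchor": "middle",
                        "fill": text_fill,
                    },
                ).text = str(vid)
            if spec.show_flags and flags:
                ET.SubElement(
                    svg,
                    "title",
                ).text = f"{label} repeat {c}: {','.join(sorted(flags))}"
        for row_idx, ordinal in spec.highlights:
            if row_idx != r or not 0 <= ordinal < arch.n_repeats:
                continue
            x = spec.label_width + ordinal * (bw + gap)
            ET.SubElement(
                svg,
                "path",
                {
                    "d": (
                        f"M {x + bw / 2:g} {y - 8:g} "
                        f"l -5 -7 l 10 0 z"
                    ),
                    "fill": "#CC0000",
                },
            )
    return ET.tostring(svg, encoding="unicode")


def write_diagram(spec: DiagramSpec, path: str | Path) -> None:
    Path(path).write_text(render_diagram(spec) + "\n")
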