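"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .haplotypes import HaploPanel, parse_variant_table


def load_uruguay_panel() -> HaploPanel:
    """A published panel of 15 Uruguayan haplogroup C1d control-region
    haplotypes in rCRS variant notation.

    All carry the diagnostic 16051G transition; several lack HVR-II data
    (blank cells), and two lack coverage at single sites, which exercises
    the pairwise complete-deletion comparison logic.
    """
    text = (
        resources.files("mtcr.data")
        .joinpath("uruguay_c1d_panel.tsv")
        .read_text(encoding="utf-8")
    )
    return parse_variant_table(text)
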