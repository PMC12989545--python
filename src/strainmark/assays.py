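"""The published qPCR assay primer sets for *Methylosinus*-style
biomonitoring of *Methylobacterium symbioticum* SB0023/3.

Three assays: *xoxF* (genus-level methanol-dehydrogenase marker, not
strain-specific), *copG* (ribbon-helix-helix CopG-domain protein) and
*ubiK* (accessory factor UbiK family protein) — the latter two being the
strain-specific biomarkers. Sequences are given 5'->3'.
"""

from __future__ import annotations

ASSAY_PRIMERS: dict[str, tuple[str, str]] = {
    "xoxF": ("GGTCGAGCTTGGGATCGTAG", "GAAGAAGGGCGAGACCAACA"),
    "copG": ("TCATCACCCAAGCCAACCAG", "TCATGGTCGATCCGTCCTCT"),
    "ubik": ("GTTCATCGCCCTTGAGGTAG", "GTTCCTTGCGAATGCGGG"),
}


def all_primers() -> dict[str, str]:
    """Flat name -> sequence map of the six assay primers."""
    out: dict[str, str] = {}
    for assay, (fwd, rev) in ASSAY_PRIMERS.items():
        out[f"{assay}_f"] = fwd
        out[f"{assay}_r"] = rev
    return out
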