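"""Bundled worked-example tables: LOAD GWAS tag SNPs and the differential
ATAC-seq peaks reported to overlap their +/-100 kb windows.

Coordinates are hg19, printed scale (the same scale on which the window
arithmetic ``pos +/- 100000`` is exact).  The neuronal panel holds the five
LOAD-vs-control differential sites from sorted neuronal nuclei that fall in
LOAD-GWAS windows; the female-glia panel holds the nine sites from the
extended female non-neuronal comparison.
"""

from __future__ import annotations

import pandas as pd

# snp_id, chrom, pos, label (nearest/locus gene)
_GWAS_TAG_SNPS = [
    ("rs9271058", "chr6", 32575406, "HLA-DRB1"),
    ("rs6024870", "chr20", 54997568, "CASS4"),
    ("rs73223431", "chr8", 27219987, "PTK2B"),
    ("rs9331896", "chr8", 27467686, "CLU"),
    ("rs7920721", "chr10", 11720308, "ECHDC3"),
    ("rs12881735", "chr14", 92932828, "SLC24A4"),
    ("rs7185636", "chr16", 19808163, "IQCK"),
    ("rs138190086", "chr17", 61538148, "ACE"),
    ("rs3752246", "chr19", 1056492, "ABCA7"),
    ("rs429358", "chr19", 45411941, "APOE"),
    ("rs12539172", "chr7", 100091795, "NYAP1 (ZCWPW1)"),
]

# printed windows (pos +/- 100 kb) for cross-checking the arithmetic
_PRINTED_WINDOWS = {
    "rs9271058": ("chr6", 32475406, 32675406),
    "rs6024870": ("chr20", 54897568, 55097568),
    "rs73223431": ("chr8", 27119987, 27319987),
    "rs9331896": ("chr8", 27367686, 27567686),
    "rs7920721": ("chr10", 11620308, 11820308),
    "rs12881735": ("chr14", 92832828, 93032828),
    "rs7185636": ("chr16", 19708163, 19908163),
    "rs138190086": ("chr17", 61438148, 61638148),
    "rs3752246": ("chr19", 956492, 1156492),
    "rs429358": ("chr19", 45311941, 45511941),
    "rs12539172": ("chr7", 99991795, 100191795),
}

# chrom, start, end, direction ("up" = more accessible in LOAD)
_NEURONAL_PANEL = [
    ("chr6", 32551592, 32552707, "up"),
    ("chr6", 32489394, 32490069, "up"),
    ("chr20", 54994099, 54994641, "down"),
    ("chr8", 27209401, 27210247, "down"),
    ("chr8", 27563212, 27563671, "down"),
]

_FEMALE_GLIA_PANEL = [
    ("chr10", 11784165, 11784736, "up"),
    ("chr14", 92966426, 92967442, "down"),
    ("chr16", 19894588, 19895301, "down"),
    ("chr17", 61627113, 61628372, "down"),
    ("chr19", 1101756, 1102160, "down"),
    ("chr19", 45416036, 45416558, "down"),
    ("chr19", 45428555, 45429362, "down"),
    ("chr19", 45454352, 45455071, "down"),
    ("chr7", 100025783, 100028055, "down"),
]


def load_gwas_tag_snps() -> pd.DataFrame:
    """The published LOAD GWAS tag SNPs that anchor the worked-example windows."""
    return pd.DataFrame(_GWAS_TAG_SNPS, columns=["snp_id", "chrom", "pos", "label"])


def load_printed_windows() -> pd.DataFrame:
    """The +/-100 kb windows as printed, keyed by tag SNP."""
    rows = [(k, *v) for k, v in _PRINTED_WINDOWS.items()]
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "window_start", "window_end"])


def load_overlap_panel(panel: str) -> pd.DataFrame:
    """Differential peaks reported inside GWAS windows.

    ``panel``: "neuronal" (LOAD vs control, sorted neuronal nuclei) or
    "female_glia" (LOAD vs control, extended female non-neuronal cohort).
    """
    if panel == "neuronal":
        rows = _NEURONAL_PANEL
    elif panel == "female_glia":
        rows = _FEMALE_GLIA_PANEL
    else:
        raise ValueError(f"unknown panel {panel!r}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
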