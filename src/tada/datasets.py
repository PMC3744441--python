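"""Small published data tables bundled for examples and validation.

The one dataset here is the published table of top ASD candidate genes from
the combined whole-exome data of 932 trios (641 with transmission calls) and
935 cases / 870 controls: per-gene loss-of-function counts (de novo,
transmitted, nontransmitted, case, control) together with the published
de-novo-only and combined-analysis p-values.  It is the worked example for
the count conventions of this package: five of the genes carry two
independent de novo LoF events, and genes such as KATNAL2 (de novo plus
case-control support) illustrate how integrating evidence streams separates
genes that de novo counts alone cannot.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_asd_top_genes", "ASD_DESIGN_SIZES"]

#: Sample sizes of the combined ASD data behind the table below.
ASD_DESIGN_SIZES = {"n_trios": 932, "n_transmission_trios": 641, "n_cases": 935, "n_controls": 870}

_ASD_TOP_GENES_TSV = """\
gene	dn	trans	nontrans	case	control	p_dn	p_tada_lof
KATNAL2	2	1	0	4	0	3.1e-6	2e-7
CHD8	2	0	0	3	0	9.5e-5	2.4e-6
LMCD1	0	2	0	0	0	1	0.067
S100G	1	0	0	3	0	0.00042	1.6e-5
DYRK1A	2	0	0	0	0	8.6e-6	4.3e-6
PPM1D	1	0	0	2	0	0.0032	0.00023
SCN2A	2	0	0	0	0	5.9e-5	2.8e-5
CUL3	1	0	0	3	0	0.004	0.00013
DEAF1	0	2	0	1	0	1	0.031
BANK1	0	1	0	4	0	1	0.0064
POGZ	2	0	0	0	0	3e-5	1.4e-5
WDR55	0	1	0	0	0	1	0.18
FAM91A1	1	0	0	0	0	0.0046	0.0019
COL25A1	1	0	0	5	0	0.0034	2.3e-5
"""


def load_asd_top_genes() -> pd.DataFrame:
    """Published LoF counts and p-values for the top ASD candidate genes."""
    return pd.read_csv(io.StringIO(_ASD_TOP_GENES_TSV), sep="\t")
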