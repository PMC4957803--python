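"""Small bundled reference inputs.

These are printed summary values from a published WT vs miR-155-knockout
macrophage microarray screen, bundled as worked-example inputs: the mature
miR-155-5p mimic sequence, a classical M2 marker panel, and the 18-gene
candidate-target report (per-gene Pearson correlation with miR-155 and fold
changes for the three screen contrasts).  They exercise the report-side
operations (significance counting, filter thresholds) on real printed numbers;
they are inputs, not values this package claims to have measured.
"""

from __future__ import annotations

import io

import pandas as pd

from .core_io import GeneSet
from .target_screen import MatureMiRNA

#: mature miR-155-5p (mimic) sequence, 5'->3'
MIR155_SEQUENCE = "UUAAUGCUAAUUGUGAUAGGGGU"


def mir155() -> MatureMiRNA:
    return MatureMiRNA(name="miR-155-5p", sequence=MIR155_SEQUENCE)


#: classical alternatively-activated (M2) macrophage markers
M2_MARKERS = ["Mrc1", "Egr2", "Ctsc", "P2ry14", "Maf", "Hnmt", "Adk", "Igf1", "Tgfbr2", "Lipa"]


def m2_marker_panel() -> GeneSet:
    return GeneSet(name="M2 markers", members=list(M2_MARKERS), direction="down")


# Published candidate miR-155 target screen summary: 18 genes up-regulated
# >= 2 FC in KO-M1 vs WT-M1 macrophages.  Columns: Pearson R of the gene's
# expression with miR-155 and its p, then FC / p for WT-M1 vs WT-M0,
# KO-M1 vs WT-M1 and KO-M1 vs KO-M0.
_TARGET_TABLE_TSV = """\
gene	r	r_p	fc_wt_m1_vs_wt_m0	p_wt_m1_vs_wt_m0	fc_ko_m1_vs_wt_m1	p_ko_m1_vs_wt_m1	fc_ko_m1_vs_ko_m0	p_ko_m1_vs_ko_m0
Bat5	-0.96	0.0001	0.51	0.0027	2.07	0.0015	1.10	0.261
Mafb	-0.95	0.0001	0.37	0.0001	2.37	0.0385	0.91	0.599
Bach1	-0.94	0.0001	0.40	0.0003	2.95	0.0082	1.09	0.559
Maf	-0.93	0.0001	0.16	0.0024	2.92	0.0221	0.49	0.023
Ptprj	-0.90	0.0003	0.50	0.0082	2.09	0.0103	1.10	0.433
Il6ra	-0.90	0.0004	0.49	0.0013	2.14	0.0162	1.21	0.441
Gpr65	-0.87	0.0008	0.52	0.0103	2.58	0.0051	1.35	0.055
Tspan14	-0.85	0.0014	0.54	0.0001	2.65	0.0008	1.36	0.027
Inpp5d	-0.84	0.0022	0.64	0.0012	2.11	0.0002	1.34	0.005
Tcf7l2	-0.83	0.0029	0.49	0.0034	2.52	0.0500	1.41	0.267
Prkar1b	-0.82	0.0034	0.61	0.0079	2.05	0.0311	1.29	0.283
Rcbtb2	-0.79	0.0058	0.20	0.0150	2.56	0.0099	0.45	0.106
Enpp1	-0.77	0.0088	0.22	0.0002	2.03	0.0100	0.42	0.032
Glul	-0.65	0.0393	0.26	0.0021	2.20	0.0264	0.56	0.036
F13a1	-0.65	0.0393	0.19	0.0333	3.71	0.0761	0.50	0.406
Jarid2	-0.64	0.0434	0.64	0.0015	2.56	0.0000	1.87	0.002
Ikbke	-0.54	0.1038	0.80	0.0780	2.15	0.0237	1.73	0.073
Olfml3	-0.26	0.4596	0.96	0.8588	2.39	0.0350	3.11	0.051
"""


def target_screen_table() -> pd.DataFrame:
    """The published 18-row candidate-target report, indexed by gene symbol."""
    return pd.read_csv(io.StringIO(_TARGET_TABLE_TSV), sep="\t", index_col="gene")
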