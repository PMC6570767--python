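"""Experimental conditions and contrasts of the combinatorial TGF-β/ZEB1 perturbation design.

The study compares MCF10A cells under eight expression conditions — four
perturbations (TGF-β treatment, TGF-β treatment in a ZEB1 knockout,
DOX-inducible ZEB1 overexpression, ZEB1 overexpression under TGF-β-receptor
inhibition by SB-431542) and their respective controls — and derives eight
treatment-minus-control contrasts from them.  Every logFC/q table in this
package is indexed by these contrasts, in this fixed order.
"""

from __future__ import annotations

#: The eight expression conditions (perturbations and controls).
CONDITIONS: tuple[str, ...] = (
    "WT",          # control
    "TGFb",        # TGF-β treatment
    "dZEB",        # CRISPR ZEB1 knockout
    "TGFb_dZEB",   # TGF-β treatment + ZEB1 knockout
    "DMSO",        # control for DOX induction / SB inhibition
    "DOX",         # doxycycline-induced ZEB1 overexpression
    "SB",          # TGF-β receptor kinase inhibitor SB-431542
    "DOX_SB",      # ZEB1 overexpression + TGF-β inhibition
)

#: The eight contrasts (treatment vs control), fixed order.
CONTRASTS: tuple[str, ...] = (
    "TGFb_vs_WT",            # response to TGF-β induction
    "DOX_vs_DMSO",           # response to ZEB1 induction
    "SB_vs_DMSO",            # response to loss of TGF-β
    "dZEB_vs_WT",            # response to loss of ZEB1
    "TGFb_dZEB_vs_dZEB",     # TGF-β induction in the absence of ZEB1
    "TGFb_vs_TGFb_dZEB",     # TGF-β induction in the presence of ZEB1
    "DOX_SB_vs_SB",          # ZEB1 induction in the absence of TGF-β
    "DOX_vs_DOX_SB",         # ZEB1 induction in the presence of TGF-β
)

N_CONTRASTS = len(CONTRASTS)

#: Contrasts used by logic-gate inference: TGF-β response with/without ZEB1
#: and ZEB1 response with/without TGF-β.
GATE_CONTRASTS = {
    "tgfb": "TGFb_vs_WT",
    "zeb1": "DOX_vs_DMSO",
    "tgfb_no_zeb1": "TGFb_dZEB_vs_dZEB",
    "zeb1_no_tgfb": "DOX_SB_vs_SB",
}

LOGFC_COLUMNS = tuple(f"logFC_{c}" for c in CONTRASTS)
Q_COLUMNS = tuple(f"q_{c}" for c in CONTRASTS)
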