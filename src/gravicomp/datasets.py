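"""Published summary tables of the altered-gravity Jurkat T-cell study.

The underlying microarray data (GEO accession GSE101102) are not bundled;
what is bundled are the small printed summary tables needed to rerun the
study's classification and concordance arithmetic as worked examples:

* the signed fold changes of the 28 annotated transcript clusters found
  hypergravity-sensitive on both the 9 g ground centrifuge and the
  suborbital rocket (concordance example: 22 same-direction, 6 reverse);
* the cross-tabulated transcript-cluster counts behind the temporal
  (75 s rocket hypergravity vs 300 s centrifuge hypergravity) and the
  flight-microgravity vs vector-averaged-gravity classifications;
* one overlap-ledger row (clinostat-upregulated TCs vs the centrifuge
  comparison) and the non-controlled cross-platform hypergravity overlap.

These are inputs for desk-scale reproduction, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "hypergravity_cross_platform_fc",
    "temporal_crosstab",
    "cross_microgravity_crosstab",
    "clinostat_up_overlap_row",
    "noncontrolled_hypergravity_overlap",
    "TC_UNIVERSE_ANALYZED",
    "SAME_RESPONSE_FLIGHT_VAG",
]

#: Transcript-cluster universe of the published two-step classifications.
TC_UNIVERSE_ANALYZED = 43395

#: TCs with the same response in flight microgravity and vag (headline <1%).
SAME_RESPONSE_FLIGHT_VAG = 9

# 28 annotated hypergravity-sensitive TCs found on both platforms:
# (gene symbol, tc_id, FC 9g centrifuge vs 1g control, FC rocket hyp-g vs 1g IF)
_HYPERGRAVITY_FC_ROWS = [
    ("ATP6V1A", "TC03000583.hg.1", 1.57, 1.34),
    ("BCAT1", "TC12001309.hg.1", 1.31, 1.35),
    ("CAT", "TC11000327.hg.1", 1.39, 1.31),
    ("CBFB", "TC16000528.hg.1", 1.60, 1.42),
    ("CERS6", "TC02000996.hg.1", 1.37, 1.42),
    ("EAF1", "TC03000096.hg.1", 1.39, 1.30),
    ("ETS1", "TC11002439.hg.1", 1.55, 1.38),
    ("G3BP1", "TC05000844.hg.1", 1.54, 1.32),
    ("GAN", "TC16000638.hg.1", 1.33, 1.35),
    ("KPNB1", "TC17000611.hg.1", 1.93, 1.61),
    ("NET1", "TC10000047.hg.1", 1.38, 1.45),
    ("NUDT3", "TC06004129.hg.1", 1.68, 1.39),
    ("PAG1", "TC08001361.hg.1", 1.32, 1.30),
    ("PELI2", "TC14000332.hg.1", 1.43, 1.36),
    ("POM121L9P", "TC05000487.hg.1", 1.42, -1.36),
    ("POM121L9P", "TC05000309.hg.1", 1.41, -1.31),
    ("POM121L9P", "TC05000321.hg.1", 1.41, -1.31),
    ("POM121L9P", "TC06000218.hg.1", 1.41, -1.31),
    ("POM121L9P", "TC06000691.hg.1", 1.41, -1.31),
    ("PRPS1", "TC0X000526.hg.1", 1.37, 1.31),
    ("RBM3", "TC0X000255.hg.1", 1.35, 1.34),
    ("RBM8A", "TC01001093.hg.1", 1.44, 1.55),
    ("RSC1A1; DDI2", "TC01000193.hg.1", 1.44, 1.32),
    ("SAMD9", "TC07001605.hg.1", -1.34, 1.35),
    ("SFT2D2", "TC01006289.hg.1", 1.72, 1.34),
    ("SRP14", "TC15001228.hg.1", 1.42, 1.41),
    ("SRSF6", "TC20000316.hg.1", 1.38, 1.39),
    ("TMED8", "TC14001343.hg.1", 1.38, 1.31),
]


def hypergravity_cross_platform_fc() -> pd.DataFrame:
    """Signed FC pairs of the 28 cross-platform hypergravity-sensitive TCs."""
    return pd.DataFrame(
        _HYPERGRAVITY_FC_ROWS,
        columns=["gene_symbol", "tc_id", "fc_centrifuge_9g", "fc_tx_hyp_g"],
    )


def temporal_crosstab() -> dict:
    """Counts of TCs by response after 75 s (rocket) x 300 s (centrifuge).

    ``cells`` lists (call_75s, call_300s, count) for TCs surviving control
    filtering; ``eliminated`` is the union of TCs removed by control
    comparisons at either stage.
    """
    return {
        "cells": [
            ("up", "up", 29),
            ("up", "down", 1),
            ("up", "none", 60),
            ("down", "down", 4),
            ("down", "up", 8),
            ("down", "none", 198),
            ("none", "up", 1011),
            ("none", "down", 448),
            ("none", "none", 40909),
        ],
        "eliminated": 727,
        "universe": TC_UNIVERSE_ANALYZED,
    }


def cross_microgravity_crosstab() -> dict:
    """Counts by response in flight microgravity x vector-averaged gravity."""
    return {
        "cells": [
            ("up", "up", 8),
            ("up", "down", 0),
            ("up", "none", 61),
            ("down", "down", 1),
            ("down", "up", 2),
            ("down", "none", 295),
            ("none", "up", 171),
            ("none", "down", 44),
            ("none", "none", 42086),
        ],
        "eliminated": 727,
        "universe": TC_UNIVERSE_ANALYZED,
    }


def clinostat_up_overlap_row() -> dict:
    """Published overlap-ledger row: clinostat-upregulated TCs (all TCs).

    Of the 181 TCs upregulated in the clinostat vs 1 g control comparison,
    171 are also upregulated in the 9 g centrifuge vs 1 g control
    comparison (94.5%).
    """
    return {
        "total": 181,
        "centrifuge_9g": {"up": 171, "down": 0, "non_responsive": 10},
    }


def noncontrolled_hypergravity_overlap() -> dict:
    """Non-controlled cross-platform hypergravity overlap: 1520 of the 5778
    centrifuge-sensitive TCs were also rocket-hypergravity-sensitive (26%)."""
    return {"overlap": 1520, "centrifuge_total": 5778}
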