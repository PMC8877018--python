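"""Small published reference tables bundled for worked examples and checks."""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["site_cwm_table", "SITE_CWM_F_PRINTED"]

# Site-level community-weighted means of seven leaf traits for eight
# tropical dry forest 0.1-ha sites (four secondary-forest SEF, four
# old-growth OGF), as printed in the source survey's summary table.
# Units: phenols/tannins mg GAE/100 g; flavonoids mg CE/100 g; chlorophyll
# SPAD units; sla cm2/g; ld g/cm3; lfm g/cm2.
_SITE_CWM = """\
site\thabitat\tphenols\ttannins\tflavonoids\tchlorophyll\tsla\tld\tlfm
LFH\tSEF\t140.47\t36.52\t26.14\t32.30\t125.47\t0.13\t0.02
NAC2\tSEF\t35.46\t9.58\t20.41\t37.39\t137.85\t0.22\t0.02
HN2\tSEF\t11.14\t4.97\t2.81\t37.37\t190.74\t0.10\t0.05
LIM1\tSEF\t31.48\t11.78\t11.54\t39.38\t149.02\t0.06\t0.02
TEJ1\tOGF\t18.97\t7.36\t10.30\t39.29\t176.94\t0.54\t0.02
TEJ2\tOGF\t31.99\t9.92\t13.83\t36.76\t174.01\t0.10\t0.03
LIM2\tOGF\t25.45\t8.71\t7.84\t34.46\t119.00\t0.11\t0.02
UNAM\tOGF\t23.89\t7.73\t7.23\t38.44\t194.59\t0.09\t0.02
"""

#: Printed habitat-contrast F statistics for the same table (one-way ANOVA
#: of the four SEF site CWMs against the four OGF site CWMs, per trait).
SITE_CWM_F_PRINTED = {
    "phenols": 1.02,
    "tannins": 1.05,
    "flavonoids": 1.04,
    "chlorophyll": 0.12,
    "sla": 0.50,
    "ld": 0.51,
    "lfm": 0.4,
}


def site_cwm_table() -> pd.DataFrame:
    """The eight-site CWM reference table, indexed by site."""
    return pd.read_csv(io.StringIO(_SITE_CWM), sep="\t", index_col="site")
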