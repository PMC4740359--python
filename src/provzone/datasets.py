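"""Published reference values for the 16-site *Stylidium hispidum* AFLP survey.

The raw band matrix for the survey was never deposited, but the per-site
summary table (coordinates, sample sizes, locally common markers, percent
polymorphic loci, expected heterozygosity) and the AMOVA sums of squares were
printed and are reproduced here.  They serve as worked-example inputs: the
variance-component, aggregation and regression code paths can be validated
against the printed results without the raw data.
"""

from __future__ import annotations

import io

import pandas as pd

from .io import SiteTable

# Sampled locations and diversity indices; south latitude / east longitude in
# decimal degrees, sample size n, locally common markers f (band in <=50% of
# populations), percent polymorphic loci, expected heterozygosity with SE.
_SITE_ROWS = """\
population,latitude,longitude,n,f_locally_common,plp,he,he_se
JCP1,-31.4907,116.1671,42,6,89.6,0.257,0.016
JCP2,-31.5076,116.2338,29,5,81.3,0.235,0.017
AV1,-31.5621,116.1818,33,7,89.6,0.247,0.015
AV2,-31.5849,116.1595,37,7,83.6,0.251,0.015
JFP1,-31.8904,116.0944,30,7,81.3,0.220,0.015
JFP2,-31.8911,116.0784,33,8,82.8,0.226,0.016
BG,-32.1826,116.0520,32,6,83.6,0.235,0.016
SERP1,-32.3826,116.0096,32,8,91.0,0.238,0.014
SERP2,-32.4001,116.0388,32,6,88.8,0.243,0.015
SCARP,-32.5517,116.0022,28,5,79.9,0.200,0.016
TOR,-32.5860,116.0472,33,6,76.1,0.213,0.016
CPC,-32.6772,116.0403,32,6,76.9,0.228,0.016
WS,-32.8302,115.9706,32,3,79.9,0.221,0.016
WD,-32.8458,115.9794,32,6,85.1,0.250,0.016
YRLP,-32.9514,115.9562,31,5,76.1,0.221,0.016
YS,-32.9584,115.9556,30,2,62.7,0.186,0.017
"""

# AMOVA over the 134 markers and 518 individuals: df and sums of squares for
# the among- and within-population strata.
REFERENCE_AMOVA = {
    "df_among": 15,
    "df_within": 502,
    "ss_among": 2574.99,
    "ss_within": 8221.85,
}

# Headline statistics of the published survey, for orientation only.
REFERENCE_GLOBAL_R = 0.687
REFERENCE_N_LOCI = 134


def load_reference_summary() -> pd.DataFrame:
    """Per-site diversity summary for the 16 study populations."""
    return pd.read_csv(io.StringIO(_SITE_ROWS))


def load_reference_sites() -> SiteTable:
    """Coordinates of the 16 study populations as a :class:`SiteTable`."""
    df = load_reference_summary()[["population", "latitude", "longitude"]]
    return SiteTable(df.copy())
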