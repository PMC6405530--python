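"""Published black locust population census.

The study's per-population sampling summary: population name, range
(native North America vs invasive Europe), WGS84 coordinates, the number
of sampled individuals N and of unique multilocus genotypes G.  These
printed values are inputs for desk-scale recomputation of the clonal
diversity statistics (no genotype-level data are included).
"""

from __future__ import annotations

import io as _io

import pandas as pd

__all__ = ["load_population_census"]

_CENSUS_CSV = """population,range_label,longitude,latitude,N,G
Barthelasse Avignon,invasive,4.818,43.965,19,18
Brno,invasive,16.518,49.042,11,5
Budapest,invasive,19.107,47.663,20,13
Carei,invasive,22.449,47.661,11,11
Corphalie,invasive,5.259,50.539,10,10
Drewnica,invasive,21.251,52.253,10,10
Gafos Galicia,invasive,-8.617,42.383,12,5
Gorna Oryahovitsa,invasive,25.694,43.119,12,12
Kelpen-Oler,invasive,5.825,51.205,12,12
Klein,invasive,9.089,49.991,11,11
La Flotte,invasive,-0.305,44.385,6,3
La Gouaneyre,invasive,-0.273,44.376,6,5
London Streat Ham,invasive,0.143,51.433,10,7
London Wandworth,invasive,0.163,51.446,10,8
Macedonia,invasive,21.571,41.507,12,12
Meppen,invasive,7.377,52.704,12,8
Montseny,invasive,2.512,41.831,12,12
Munchenberg,invasive,14.046,52.559,12,4
Novi Pazar-Kulevcha,invasive,27.195,43.345,12,12
Nyirsegi,invasive,19.041,47.581,12,12
Obermeidenrich,invasive,6.816,51.476,12,12
Pinczow,invasive,20.702,50.265,10,10
Poznan,invasive,16.808,52.311,12,12
Priesterweg Naturpark,invasive,13.358,52.461,12,12
Pusztavacs,invasive,19.506,47.172,10,10
Remy,invasive,2.675,49.460,12,8
Rhodos,invasive,27.944,36.287,12,9
Slovakia,invasive,19.867,48.720,12,12
Szczecin,invasive,14.548,53.337,12,12
Turkey,invasive,32.904,40.159,11,11
Uden,invasive,5.618,51.685,11,5
Valencia,invasive,-0.784,39.397,19,6
Vitoria,invasive,-1.942,43.216,13,13
Wien,invasive,16.473,48.252,12,12
ALTOONA,native,-78.383,40.489,11,10
Barbours Creek,native,-80.110,37.580,21,20
Blue Ridge,native,-82.672,35.457,22,21
CAMP CREEK,native,-81.103,37.488,12,12
CHATTANOOGA,native,-85.783,35.120,12,11
DANIEL BOONE NF,native,-83.645,37.751,12,12
Eriline,native,-83.540,37.040,22,22
FAYETTEVILLE,native,-94.205,36.071,10,9
FORT MILL RIDGE,native,-78.797,39.327,12,12
FORT SMITH,native,-94.290,35.343,12,10
Ironton,native,-82.460,38.800,22,17
LEWISBURG,native,-80.381,37.783,7,7
Locust Cove,native,-83.710,35.360,22,18
Morehead,native,-83.466,38.091,22,19
OUACHITA,native,-93.837,34.449,12,9
Perry,native,-78.660,39.000,22,22
Pleasant Hill,native,-93.460,35.590,4,3
SHOOTING CREEK,native,-83.628,35.055,11,11
Slatyfork,native,-80.000,38.180,17,17
Stokesville,native,-79.300,38.280,22,22
US GRP 1,native,-78.750,39.650,15,15
US GRP 2,native,-81.100,39.067,11,11
US GRP 3,native,-79.933,37.267,6,6
US GRP 4,native,-84.500,38.033,6,6
US GRP 5,native,-84.533,38.650,8,8
US GRP 6,native,-83.683,36.750,7,7
Victor,native,-93.050,35.650,22,17
WAYNE NF,native,-82.594,38.658,12,12
Whiteop,native,-81.656,36.769,22,20
"""


def load_population_census() -> pd.DataFrame:
    """The 63-population census as a DataFrame.

    Columns: population, range_label ('native' = North America,
    'invasive' = Europe), longitude, latitude, N (sampled individuals),
    G (unique multilocus genotypes).
    """
    return pd.read_csv(_io.StringIO(_CENSUS_CSV))
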