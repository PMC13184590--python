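"""pahfire: wildfire contribution to PAH concentrations and cancer risk.

A desk-scale pipeline: emission-inventory speciation redistribution,
a per-cell gas/particle fate box model, baseline-vs-no-wildfire scenario
attribution, and ILCR/TPUM health-risk metrics, with a synthetic-data
generator so everything runs without external inputs.
"""

from importlib import resources

__version__ = "0.1.0"


def default_species_table_path():
    """Path to the packaged default species property table (CSV)."""
    return resources.files("pahfire") / "data" / "species_default.csv"


def default_regions_path():
    """Path to the packaged default region-box table (CSV)."""
    return resources.files("pahfire") / "data" / "regions_default.csv"
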