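"""Shared constants: species, biomass components, soil compartments, pools."""

SPECIES = ("spruce", "pine", "birch")

#: The eight tree biomass components (dry mass).
#: SW stem wood, BR branches, DB dead branches, SB stem bark, SU stump,
#: FL foliage, RF fine roots, RC coarse roots.
COMPONENTS = ("SW", "BR", "DB", "SB", "SU", "FL", "RF", "RC")

#: Components counted as above-ground biomass; the remainder is below ground.
AGB_COMPONENTS = ("SW", "BR", "DB", "SB", "SU", "FL")
BGB_COMPONENTS = ("RF", "RC")

#: Soil chemical compartments: acid-hydrolyzable (celluloses), water-soluble
#: (sugars), ethanol-soluble (waxes), non-soluble (lignin-like), humus.
COMPARTMENTS = ("A", "W", "E", "N", "H")
AWEN = ("A", "W", "E", "N")

#: The five reported carbon pools.
POOLS = ("AGB", "BGB", "litter", "deadwood", "SO")

#: Dry biomass to carbon conversion.
CARBON_FRACTION = 0.5

#: Default inventory timeframe (both epochs inclusive).
EPOCH_START = 2001
EPOCH_END = 2016

#: Grid cell side (m) chosen so the cell area matches the field-plot area.
CELL_SIDE = 15.26
PLOT_AREA = 232.9  # m^2

#: Background annual stem mortality applied when stem counts do not decrease.
DEFAULT_MORTALITY_RATE = 0.004

#: Fraction of stem wood extracted at harvest (the rest becomes litter).
HARVEST_SW_EXTRACTION = 0.95

#: Year of the stand map used for AGE bookkeeping.
STAND_MAP_YEAR = 2018
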