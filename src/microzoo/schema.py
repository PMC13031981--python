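"""Shared vocabularies, column schemas, and exception types.

The pipeline tracks four microzooplankton groups: ciliates and
dinoflagellates, each split at a 20 um major-axis threshold into a small
(<20 um) and a large (>=20 um) size class. Biomass is carried in ug C per
litre throughout.
"""

from __future__ import annotations

#: Taxon groups distinguished in micrographs.
TAXON_DINO = "dinoflagellate"
TAXON_CILIATE = "ciliate"
TAXON_TRIPOS = "tripos"  # reported separately, excluded from group totals
TAXA = (TAXON_DINO, TAXON_CILIATE, TAXON_TRIPOS)

#: The four biomass groups (taxon x size class) used by community statistics.
GROUP_COLUMNS = ("dino_small", "dino_large", "cil_small", "cil_large")

SEASONS = ("winter", "summer")
REGIONS = ("inner", "mid", "outer")

SIZE_CLASS_SMALL = "<20um"
SIZE_CLASS_LARGE = ">=20um"

#: Metadata columns of a biomass table (rows are station-visit samples).
META_COLUMNS = ("year", "season", "region")


def group_column(taxon: str, size_class: str) -> str:
    """Map (taxon, size class) to its biomass-table column name."""
    prefix = {TAXON_DINO: "dino", TAXON_CILIATE: "cil"}.get(taxon)
    if prefix is None:
        raise KeyError(f"no biomass column for taxon {taxon!r}")
    suffix = "small" if size_class == SIZE_CLASS_SMALL else "large"
    return f"{prefix}_{suffix}"


class MicrozooError(Exception):
    """Base class for errors raised by this package."""


class InputError(MicrozooError, ValueError):
    """Invalid user-supplied values (non-positive lengths, bad shapes...)."""


class PlacementError(MicrozooError, RuntimeError):
    """Synthetic cells could not be placed without overlap."""


class DegenerateShapeError(MicrozooError, ValueError):
    """A region is too small or thin for moment-based axis measurement."""


class StateError(MicrozooError, RuntimeError):
    """An operation was applied in an invalid order (e.g. double correction)."""


class ConfigurationError(MicrozooError, KeyError):
    """Missing model coefficients or malformed configuration."""


class InconsistentDilutionError(MicrozooError, ValueError):
    """Diluted treatment is not actually diluted (x >= 1)."""


class InsufficientReplicationError(MicrozooError, ValueError):
    """Fewer than two replicates on one side of a comparison."""


class UndefinedCompositionError(MicrozooError, ValueError):
    """Relative biomass requested for an all-zero sample."""


class ConstantColumnError(MicrozooError, ValueError):
    """A column with zero variance cannot be z-scored."""


class RankDeficientError(MicrozooError, ValueError):
    """Explanatory matrix is rank deficient; screen co-correlated variables."""
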