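"""Exception hierarchy for gardenflow.

Validation problems (bad configuration, malformed inputs) are kept distinct
from compute-time failures (disconnected circuit, degenerate statistics) so
callers — and the CLI exit codes — can tell them apart.
"""


class GardenflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GardenflowError):
    """A parameter is outside its allowed range or inconsistent."""


class SchemaError(GardenflowError):
    """An input table or raster does not match the expected schema."""


class GenerationError(GardenflowError):
    """The synthetic-scenario generator cannot satisfy its constraints."""


class ConvergenceError(GardenflowError):
    """A model fit failed to converge (e.g. complete separation)."""


class DisconnectedNodesError(GardenflowError):
    """Source and target fall in different connected components."""


class SolverError(GardenflowError):
    """The linear solve failed or left an unacceptable residual."""


class DegenerateInputError(GardenflowError):
    """An input has no variation where variation is required
    (constant covariate, zero-variance map, unsplittable tertiles)."""
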