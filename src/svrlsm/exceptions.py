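"""Exception hierarchy for cohort-analysis failures.

All exceptions derive from :class:`SvrLsmError` so callers can catch
package failures distinctly from programming errors; each subclass maps
to one failure mode a pipeline stage can hit.
"""


class SvrLsmError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SvrLsmError, ValueError):
    """A single record or argument violates its contract."""


class UndefinedTestError(SvrLsmError, ValueError):
    """A statistical test cannot be formed (e.g., an empty contingency cell)."""


class InvalidCohortError(SvrLsmError, ValueError):
    """The cohort as a whole cannot support the requested analysis."""


class CohortGeometryError(SvrLsmError, ValueError):
    """Lesion masks do not share one voxel grid and affine."""


class EmptyMatrixError(SvrLsmError, ValueError):
    """No voxel survives the inclusion filter."""


class DegenerateCovariateError(SvrLsmError, ValueError):
    """A covariate column is constant or the covariate matrix is rank-deficient."""


class ConfigError(SvrLsmError, ValueError):
    """A configuration object is internally inconsistent."""
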