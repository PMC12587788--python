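"""Exception hierarchy.

Validation failures (bad user input, malformed files, infeasible designs)
derive from :class:`ValidationError`; statistical degeneracies that a caller
may want to catch and downgrade to "not assessable" derive from
:class:`UndefinedStatisticError`.
"""


class CieagreeError(Exception):
    """Base class for all package errors."""


class ValidationError(CieagreeError, ValueError):
    """Invalid input value, schema violation, or infeasible configuration."""


class InsufficientDataError(CieagreeError):
    """Too few paired observations for the requested analysis."""


class UndefinedStatisticError(CieagreeError):
    """The requested statistic is undefined for the given data
    (e.g. both reading sets constant and identical)."""


class DegenerateCIError(UndefinedStatisticError):
    """A confidence interval cannot be formed (e.g. CCC exactly +/-1).

    For a point estimate of exactly +/-1 the Fisher-z transform diverges;
    report the point estimate alone or perturb/bootstrap instead.
    """


class InfeasibleDesignError(ValidationError):
    """Sample-size design with expected CCC not exceeding the null CCC."""
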