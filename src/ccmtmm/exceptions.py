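"""Exception and warning types used across the package."""


class CcmtmmError(Exception):
    """Base class for all package-specific errors."""


class DataError(CcmtmmError):
    """Malformed or degenerate input data (bad scores, empty tables, ...)."""


class DesignError(CcmtmmError):
    """Rating design violates the requirements of the requested model."""


class ConfigError(CcmtmmError):
    """Invalid configuration (model spec, estimation settings, CLI config)."""


class EstimationError(CcmtmmError):
    """Estimation could not be carried out (as opposed to not converging)."""


class ConvergenceWarning(UserWarning):
    """An estimator finished without meeting its convergence criterion."""


class DesignWarning(UserWarning):
    """A design feature is legal but likely unintended or weakly identified."""
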