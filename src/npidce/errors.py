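"""Exception hierarchy shared across the package."""


class NpidceError(Exception):
    """Base class for all package-specific errors."""


class DesignError(NpidceError, ValueError):
    """Invalid design dimensions or an infeasible design request."""


class EncodingError(NpidceError, ValueError):
    """Unknown attribute level or malformed encoded vector."""


class DataError(NpidceError, ValueError):
    """Choice data violating the long-format panel invariants."""


class ConfigError(NpidceError, ValueError):
    """Inconsistent simulation or estimation configuration."""


class FitError(NpidceError, RuntimeError):
    """Estimation failure that must not produce silent output."""


class WTPError(NpidceError, ValueError):
    """Ill-posed willingness-to-pay request (e.g. non-negative fee coefficient)."""
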