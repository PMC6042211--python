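"""Exception hierarchy.

All locohcv errors derive from :class:`LocohError` so the CLI can map them
to exit status 1 with a single actionable message; usage errors (bad flags)
are handled by click and exit with status 2.
"""


class LocohError(Exception):
    """Base class for all data/parameter/configuration errors."""


class ConfigurationError(LocohError):
    """A config file or column mapping is unusable."""


class InputError(LocohError):
    """Input data violate a precondition (too few fixes, duplicate timestamps...)."""


class ParameterError(LocohError):
    """A numeric parameter is out of its legal range."""


class DegenerateHullsetError(ParameterError):
    """A hullset has (near-)zero total area and cannot act as a density."""
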