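"""Exception hierarchy for scgdyn."""


class ScgdynError(Exception):
    """Base class for all scgdyn errors."""


class GraphError(ScgdynError):
    """Malformed or structurally unsuitable directed graph."""


class ParameterError(ScgdynError, ValueError):
    """Invalid user-supplied parameter value."""


class GenerationError(ScgdynError):
    """Random construction failed within its retry budget."""


class ConfigurationError(ScgdynError):
    """Inconsistent simulation inputs (e.g. an edge without a lag)."""


class InsufficientDataError(ScgdynError):
    """Too few spikes/intervals for the requested analysis."""


class DegenerateSignalError(ScgdynError):
    """Signal carries no variance at all (all eigenvalues zero)."""
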