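"""Exception hierarchy shared by all analysis stages."""


class RespstabError(Exception):
    """Base class for all errors raised by respstab."""


class InputError(RespstabError, ValueError):
    """A file, trace, or parameter violates a precondition."""


class AnalysisError(RespstabError, RuntimeError):
    """The input was well-formed but the analysis cannot proceed
    (e.g. no oscillation detected, too few cycles for a section)."""
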