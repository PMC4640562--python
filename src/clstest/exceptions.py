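"""Exception hierarchy for clstest."""


class ClstestError(Exception):
    """Base class for all clstest errors."""


class InputError(ClstestError):
    """A required input file is missing or unreadable."""


class FormatError(ClstestError):
    """An input file parses but violates the expected format/contract."""


class ValidationError(ClstestError):
    """A value violates a documented invariant (e.g. 0-based position)."""


class UndefinedScoreError(ClstestError):
    """The CLS is undefined (n = 0); callers should report no-test."""


class GenerationError(ClstestError):
    """The fixture generator was asked for an unsatisfiable configuration."""


class SearchError(ClstestError):
    """A design search exhausted its ceiling without meeting the target."""
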