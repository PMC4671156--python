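"""Exception hierarchy for desirank.

All package-specific failures derive from :class:`DesirankError`, so callers
(including the CLI) can catch a single base class and translate it into a
nonzero exit with a machine-readable message.
"""

from __future__ import annotations


class DesirankError(Exception):
    """Base class for all desirank errors."""


class InvalidSpecError(DesirankError, ValueError):
    """A desirability-function specification violates its invariants."""


class InvalidWeightsError(DesirankError, ValueError):
    """A weight vector is unusable (negative, non-finite, or all zero)."""


class UnknownCategoryError(DesirankError, KeyError):
    """A categorical value has no mapping and the spec demands an error."""


class ConfigError(DesirankError, ValueError):
    """A criteria/run configuration is invalid.

    Carries a list of individual problems so that validation can report
    every error at once rather than failing on the first.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
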