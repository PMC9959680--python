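"""Exception hierarchy for radqsar.

Every error raised on bad user input derives from :class:`RadqsarError` so
callers (and the CLI) can catch one base class.
"""


class RadqsarError(Exception):
    """Base class for all radqsar errors."""


class FormatError(RadqsarError):
    """A delimited-text file is structurally malformed (e.g. missing header)."""


class ValidationError(RadqsarError):
    """A table violates its invariants (non-numeric cell, duplicate id, ...)."""


class AlignmentError(RadqsarError):
    """Two tables or a model and a table disagree on ids or columns."""


class DegenerateInputError(RadqsarError):
    """Input too small or too flat for the operation (n < 2, all-constant, ...)."""


class SingularityError(RadqsarError):
    """A design matrix is rank deficient; message names the collinear columns."""


class DegreesOfFreedomError(RadqsarError):
    """Not enough observations for the requested statistic (n <= p)."""


class SplitError(RadqsarError):
    """A train/test split request produces an unusable partition."""


class SearchSpaceError(RadqsarError):
    """The descriptor-subset search space is too small to search."""


class TrainingError(RadqsarError):
    """Neural-network training produced a non-finite objective."""
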