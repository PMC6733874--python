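"""Exception hierarchy shared across the pipeline."""


class PhenoscreenError(Exception):
    """Base class for all phenoscreen errors."""


class InvalidInputError(PhenoscreenError, ValueError):
    """Structurally invalid input (bad shapes, empty event lists, bad config)."""


class DegenerateInputError(PhenoscreenError, ValueError):
    """Input is structurally valid but statistically degenerate (zero variance,
    all-zero motion index, identical group means)."""


class InvalidWindowError(PhenoscreenError, ValueError):
    """A stimulus window does not overlap the profile's time support."""


class MissingDataError(PhenoscreenError, ValueError):
    """Required rows/annotations are absent (e.g. a hit compound with no retest)."""
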