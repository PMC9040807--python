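"""Exception hierarchy for lysotrack."""


class LysotrackError(Exception):
    """Base class for all lysotrack errors."""


class FormatError(LysotrackError):
    """An input file does not conform to its expected format."""


class CoordinateValidationError(LysotrackError):
    """Prophage coordinates are internally inconsistent (duplicates, overlaps,
    unknown scaffolds)."""


class ScenarioError(LysotrackError):
    """A simulation scenario violates its own constraints."""


class AlignerNotFoundError(LysotrackError):
    """No supported short-read aligner executable is on PATH."""


class AlignmentError(LysotrackError):
    """An external alignment command failed."""


class ComputationError(LysotrackError):
    """A statistic is undefined for the given inputs (e.g. zero-length
    alignment)."""
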