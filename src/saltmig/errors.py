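"""Exception hierarchy for saltmig."""


class SaltmigError(Exception):
    """Base class for all saltmig errors."""


class TrackFormatError(SaltmigError, ValueError):
    """A track table is malformed (missing column, bad dialect, unparsable row)."""


class TrackValidationError(SaltmigError, ValueError):
    """A track table parses but violates a semantic invariant (e.g. duplicate timepoints)."""


class ParameterError(SaltmigError, ValueError):
    """An analysis or simulation parameter is out of its valid range."""
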