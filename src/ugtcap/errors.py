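"""Exception hierarchy shared by all ugtcap modules."""


class UgtcapError(Exception):
    """Base class for all domain errors raised by ugtcap."""


class ParseError(UgtcapError):
    """A structure file could not be parsed; the message names the line."""


class GeometryError(UgtcapError):
    """A geometric precondition failed (missing hydroxyl, bad reference...)."""


class FitError(UgtcapError):
    """The capacity model cannot be fitted to the given panel."""
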