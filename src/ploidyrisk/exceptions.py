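"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A simulation or analysis configuration violates an invariant.

    The message names the offending field.
    """


class ParseError(ValueError):
    """A table on disk is malformed; the message carries the line/row number."""


class InadequateSampleError(ValueError):
    """A sample cannot be analysed (e.g. too few internal control nuclei)."""


class DataError(ValueError):
    """Inconsistent patient data (e.g. endpoint date before index date)."""
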