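"""Exception types raised by the sscore package."""


class SScoreError(Exception):
    """Base class for all sscore errors."""


class ValidationError(SScoreError, ValueError):
    """Invalid input data: duplicate identifiers, unparseable cells,
    referential failures between tables."""


class DegenerateInputError(SScoreError, ValueError):
    """An input that is syntactically fine but statistically unusable,
    e.g. a constant score distribution or an empty gene universe."""
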