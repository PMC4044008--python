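"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """An input file violates its declared format."""


class DuplicateRecordError(FormatError):
    """Two records in one file share an identifier."""


class ValidationError(ValueError):
    """Input values are well-formed but semantically invalid."""


class GenerationError(RuntimeError):
    """The synthetic-data generator could not satisfy its placement constraints."""
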