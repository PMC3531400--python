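"""Exception hierarchy for configuration loading and model validation."""


class AfhsError(Exception):
    """Base class for all model errors; maps to CLI exit code 1."""


class SchemaError(AfhsError):
    """A required column or header is missing, or the schema version is wrong."""


class IntegrityError(AfhsError):
    """A table-level invariant is violated (e.g. wrong registry cardinality)."""


class ValidationError(AfhsError):
    """A field value is out of range or inconsistent; message names row/field."""
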