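"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (thresholds, simulation setup, CLI options)."""


class FormatError(ValueError):
    """Malformed input file (bad counts, missing fields, unsorted records)."""


class TruthError(ValueError):
    """Inconsistent simulation ground truth (e.g. mutant multiplicity exceeding copy number)."""


class NotEvaluableError(ValueError):
    """An operation was asked about a record lacking the required context."""
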