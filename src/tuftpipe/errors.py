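"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """Invalid run or task configuration."""


class FormatError(ValueError):
    """On-disk artifact is corrupt or violates its schema."""


class ValidationError(ValueError):
    """In-memory object violates a documented invariant."""


class ConsistencyError(ValueError):
    """Cross-referenced ids or shapes do not agree."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. a constant movie)."""


class InsufficientDataError(ValueError):
    """Too few trials, triggers, or control windows for the requested analysis."""
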