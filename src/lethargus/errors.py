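"""Exception types shared across the package."""


class AnalysisError(ValueError):
    """Raised when an analysis has no qualifying input (no bouts, no
    transitions, no pairs) rather than malformed input."""


class ForegroundNotFoundError(RuntimeError):
    """Raised when no worm-like foreground can be detected in an image stack."""
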