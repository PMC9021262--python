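"""Exception hierarchy shared across the pipeline.

Validation problems (bad config, malformed inputs) and estimation
failures (rank deficiency, singular systems) are kept distinct so the
CLI can map them to different exit codes.
"""


class ValidationError(ValueError):
    """Raised for invalid configuration or malformed input data."""


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated from otherwise valid inputs."""
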