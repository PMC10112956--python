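"""Exception hierarchy.

``ValidationError`` signals bad inputs or configuration (CLI exit code 2);
``ComputationError`` signals a failure arising during an otherwise valid
computation, e.g. no finite-cost segmentation exists (CLI exit code 3).
"""


class RohsegError(Exception):
    """Base class for all rohseg errors."""


class ValidationError(RohsegError, ValueError):
    """Invalid input data, configuration, or argument combination."""


class ComputationError(RohsegError, RuntimeError):
    """A valid request that cannot be satisfied by the computation."""
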