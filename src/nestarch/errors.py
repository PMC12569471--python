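"""Exception hierarchy for nestarch."""


class NestarchError(Exception):
    """Base class for all nestarch errors."""


class ValidationError(NestarchError):
    """Invalid input data (bad enum state, ordering violation, missing field)."""


class AlignmentError(NestarchError):
    """Labels of two objects (tree, trait table, covariates) do not match."""


class NumericalError(NestarchError):
    """A matrix is singular / ill-conditioned beyond what the method tolerates."""
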