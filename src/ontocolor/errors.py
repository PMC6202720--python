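"""Exception types shared across the pipeline stages."""


class OntocolorError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OntocolorError):
    """Malformed or empty input (pixel grids, mismatched sample lengths, bad config)."""


class NoDominantColorError(OntocolorError):
    """No palette entry exceeds the dominance threshold; the image cannot be scored."""


class InsufficientDataError(OntocolorError):
    """A statistical group has too few members for the requested test."""


class DegenerateInputError(OntocolorError):
    """Input with zero variance (or otherwise degenerate) where variation is required."""


class TreeError(OntocolorError):
    """Tree parsing or validation failure."""


class UnknownTipError(TreeError):
    """A requested tip label is not present in the tree."""


class BindingError(OntocolorError):
    """Tree tips and trait matrix rows do not cover each other exactly."""

    def __init__(self, missing_states=(), extra_species=()):
        self.missing_states = tuple(missing_states)
        self.extra_species = tuple(extra_species)
        parts = []
        if self.missing_states:
            parts.append(f"tips without a state: {sorted(self.missing_states)}")
        if self.extra_species:
            parts.append(f"states without a tip: {sorted(self.extra_species)}")
        super().__init__("; ".join(parts) or "tree/trait mismatch")


class InvalidRateError(OntocolorError):
    """Rate matrix violates Q constraints (row sums, sign pattern, symmetry)."""


class InvalidStateError(OntocolorError):
    """A state label or index outside the character's state space."""


class ConvergenceError(OntocolorError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class SamplingError(OntocolorError):
    """Rejection sampler exhausted its attempt budget on some branch."""
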