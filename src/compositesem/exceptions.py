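"""Exception and warning types used across the package."""


class SpecificationError(ValueError):
    """The declarative model description violates a structural rule."""


class IdentificationError(SpecificationError):
    """The requested parameterization is not identified."""


class OverparameterizedModelError(SpecificationError):
    """More free parameters than non-redundant sample moments."""


class InputError(ValueError):
    """Invalid data input (asymmetric matrix, missing sample size, ...)."""


class CyclicModelError(ValueError):
    """The coefficient matrix cannot be inverted (cyclic structure)."""


class NotNestedError(ValueError):
    """Chi-square difference test requested for non-nested models."""


class DegenerateSolutionError(ValueError):
    """A fitted loading matrix is singular; weights cannot be recovered."""


class ConvergenceWarning(UserWarning):
    """Estimation did not reach the requested precision."""


class HeywoodWarning(UserWarning):
    """An implied variance is non-positive (inadmissible region)."""


class SingularMomentsWarning(UserWarning):
    """Sample moments are (near) singular, e.g. n < number of variables."""
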