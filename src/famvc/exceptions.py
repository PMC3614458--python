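"""Exception types shared across famvc modules."""


class FamvcError(Exception):
    """Base class for famvc errors."""


class EmptyRegionError(FamvcError):
    """No usable variants remain in the tested region."""


class PedigreeError(FamvcError):
    """Invalid pedigree (cycles, missing parents, duplicate ids)."""


class DimensionError(FamvcError):
    """Mismatched shapes or sample orderings between inputs."""


class ConvergenceError(FamvcError):
    """Variance-component optimisation failed to converge."""
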