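"""Exception types raised by the phantom generator."""


class PhantomError(Exception):
    """Base class for all oaphantom errors."""


class InvalidArgumentError(PhantomError, ValueError):
    """An argument violates a documented precondition."""


class CorruptInputError(PhantomError, IOError):
    """An on-disk volume does not match its declared geometry."""


class UnknownLabelError(PhantomError, ValueError):
    """A voxel carries a tissue code absent from the label table."""

    def __init__(self, code: int):
        self.code = int(code)
        super().__init__(f"unknown tissue code {code} not present in label table")


class PlacementFailureError(PhantomError, RuntimeError):
    """The lesion-site candidate pool was exhausted before all lesions were placed."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} lesions before the "
            "candidate pool was exhausted"
        )


class PlacementConflictError(PhantomError, RuntimeError):
    """A lesion would overwrite protected tissue (skin, nipple, muscle, background)."""


class NoIndicatorError(PhantomError, RuntimeError):
    """A reaction-diffusion solve has a connected region without any indicator tissue."""


class InfeasibleDrawError(PhantomError, RuntimeError):
    """Sampled chromophore fractions leave a negative complement after bounded retries."""


class EmptyVolumeError(PhantomError, ValueError):
    """A metric was requested on a volume containing no breast tissue."""
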