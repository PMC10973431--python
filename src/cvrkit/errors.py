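"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Input data violates a documented contract (bad units, shapes, rank, ...)."""


class InputDiscoveryError(FileNotFoundError):
    """A required BIDS / fMRIPrep-derivative input could not be resolved.

    The message enumerates every missing or ambiguous piece so the user can
    fix the dataset in one pass.
    """
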