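"""Declared error types shared across the pipeline stages."""


class GpcrnetError(Exception):
    """Base class for all declared pipeline errors."""


class InputError(GpcrnetError):
    """An input file is missing or unreadable."""


class EmptyStructureError(GpcrnetError):
    """A coordinate file yielded zero parsed atoms."""


class RadiusLookupError(GpcrnetError):
    """An element has no van der Waals radius and no fallback is configured."""


class LigandMissingError(GpcrnetError):
    """A ligand-dependent operation was requested on a ligand-free structure."""


class GraphTooSmallError(GpcrnetError):
    """The closeness formula is undefined for graphs with fewer than two nodes."""


class GenerationError(GpcrnetError):
    """A synthetic design could not be realised as geometry matching its target."""
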