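"""Exception hierarchy used across the package."""


class ShellpickError(Exception):
    """Base class for all shellpick errors."""


class FormatError(ShellpickError):
    """A trajectory or spectrum file could not be parsed."""


class TopologyError(ShellpickError):
    """The solute/solvent topology declaration is invalid."""


class FrameMismatchError(ShellpickError):
    """Frames of one trajectory disagree on atom count or composition."""


class FitDegeneracyError(ShellpickError):
    """The superposition subset is too small or collinear to define a fit."""


class EmptyShellError(ShellpickError):
    """No solvent molecule falls inside the solute ellipsoid in any frame."""


class InfeasibleReductionError(ShellpickError):
    """The requested per-center retention counts cannot be satisfied."""


class SpectrumError(ShellpickError):
    """Invalid spectrum input (empty, all-zero, or mismatched grids)."""


class GridMismatchError(SpectrumError):
    """Spectra to be combined do not share a common wavenumber grid."""
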