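"""Exception hierarchy shared across the package."""


class HelixOrderError(Exception):
    """Base class for all errors raised by helixorder."""


class SpectrumParseError(HelixOrderError):
    """Malformed spectrum/isotherm file; message names the offending line."""


class EmptyWindowError(HelixOrderError):
    """Requested spectral window does not intersect the grid."""


class DegenerateInputError(HelixOrderError):
    """Input is degenerate for the requested operation (e.g. all-zero spectrum)."""


class ParameterError(HelixOrderError):
    """Invalid parameter combination (bad smoothing window, cutoffs, grids...)."""


class SeedingError(HelixOrderError):
    """Band seeds violate the minimum-separation constraint."""


class NonConvergenceError(HelixOrderError):
    """Band fit failed to converge; carries the last iterate when available."""

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class GeometryError(HelixOrderError):
    """Ill-defined molecular geometry (zero-length bond vector, bad box...)."""


class SelectionError(HelixOrderError):
    """Atom selection matched nothing."""


class LeafletError(HelixOrderError):
    """Headgroup atoms do not split into two leaflets."""


class SingularGeometryError(HelixOrderError):
    """Transition-dipole angle at/straddling the magic angle: P2(cos alpha) = 0."""


class PipelineError(HelixOrderError):
    """A multi-stage pipeline failed; message names the stage/side."""


class GeneratorSpecError(HelixOrderError):
    """Inconsistent synthetic-data generator specification."""
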