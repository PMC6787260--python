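"""Exception and warning types raised across the package."""


class FcsFlimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FcsFlimError):
    """A simulator or pipeline configuration is invalid."""


class DecodingError(FcsFlimError):
    """A photon stream cannot be decoded into the requested raster."""


class StreamIntegrityError(FcsFlimError):
    """Event or marker times violate the monotonicity contract."""


class FormatError(FcsFlimError):
    """A container file is missing a required dataset or attribute."""


class DegenerateStreamError(FcsFlimError):
    """A simulation would produce a stream with no photon sources at all."""


class MembraneNotFoundError(FcsFlimError):
    """No membrane peak is detectable in a line-scan matrix."""


class EdgeClippingError(FcsFlimError):
    """The membrane peak sits too close to the scan edge for the aperture."""


class NormalizationError(FcsFlimError):
    """An intensity trace cannot be normalised (zero mean)."""


class InsufficientDataError(FcsFlimError):
    """Too few photons to attempt a decay fit."""


class SegmentationError(FcsFlimError):
    """No single cell could be segmented from the image."""


class UndefinedRatioError(FcsFlimError):
    """A PM/Cyt ratio is undefined (empty mask or non-positive denominator)."""


class UndefinedEfficiencyError(FcsFlimError):
    """Dimerisation efficiency is undefined (zero acceptor concentration)."""


class ImplausibleGeometryWarning(UserWarning):
    """A focal-volume fit returned an aspect ratio S < 1."""


class IllConditionedWarning(UserWarning):
    """A K_D fit was attempted on a too-narrow concentration range."""


class EmptyMapWarning(UserWarning):
    """A per-pixel map has no valid pixels after photon thresholding."""


class MaskedPixelsWarning(UserWarning):
    """More than 5% of in-cell pixels were masked out of a ratio map."""
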