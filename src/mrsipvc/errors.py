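"""Exception hierarchy for the MRSI postprocessing pipeline."""


class MrsiPvcError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(MrsiPvcError, ValueError):
    """Acquisition geometry is inconsistent or non-physical."""


class DoubleAdjustmentError(MrsiPvcError, ValueError):
    """Tissue fractions were already PSF-adjusted."""


class NoPeakError(MrsiPvcError, ValueError):
    """Kernel has no unique maximum; a width cannot be measured."""


class ShapeError(MrsiPvcError, ValueError):
    """Field shapes or grids are incompatible."""


class UnknownMetaboliteError(MrsiPvcError, KeyError):
    """No CRLB field exists for the requested metabolite."""


class MissingReferenceError(MrsiPvcError, KeyError):
    """The tCr reference CRLB field is absent from the QA bundle."""


class InsufficientDataError(MrsiPvcError, ValueError):
    """Too few voxels survive exclusions for a stable regression."""


class MissingT1Error(MrsiPvcError, KeyError):
    """A required (metabolite, tissue) T1 entry is missing."""

    def __init__(self, metabolite: str, tissue: str):
        super().__init__(f"no T1 entry for metabolite {metabolite!r}, tissue {tissue!r}")
        self.metabolite = metabolite
        self.tissue = tissue


class InvalidTransformError(MrsiPvcError, ValueError):
    """An affine matrix is singular or a displacement field is non-finite."""


class PhantomSpecError(MrsiPvcError, ValueError):
    """A phantom specification is contradictory or out of bounds."""


class ValidationError(MrsiPvcError, ValueError):
    """A table or configuration file failed validation."""


class FormatError(MrsiPvcError, ValueError):
    """A volume file could not be read."""
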