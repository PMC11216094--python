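"""Exception hierarchy shared across the package."""


class HalBDEError(Exception):
    """Base class for all package-specific errors."""


class RegistryLookupError(HalBDEError, KeyError):
    """An unknown skeleton, halogen, or transfer-group identifier."""


class AssemblyError(HalBDEError):
    """Template + group substitution produced an unparsable structure."""


class SmilesParseError(HalBDEError, ValueError):
    """A SMILES string could not be parsed under the package's valence convention."""


class BDEParseError(HalBDEError, ValueError):
    """A fixture cell is neither numeric nor a recognised missing-value sentinel."""


class IntegrityError(HalBDEError):
    """A fixture violates a structural invariant (duplicate keys, wrong shape)."""


class DegenerateScaleError(HalBDEError, ValueError):
    """Min-max scaling requested on constant input."""


class InsufficientDataError(HalBDEError, ValueError):
    """Too few matched pairs to fit a cross-halogen regression."""


class FeaturizationError(HalBDEError):
    """Atom descriptor computation failed."""


class DivergenceError(HalBDEError, RuntimeError):
    """Training loss became non-finite."""
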