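"""Exception types shared across the package."""


class LaminafluctError(ValueError):
    """Base class for all package-specific errors."""


class GeometryError(LaminafluctError):
    """A geometric precondition is violated (ellipse outside frame, contour out of bounds, degenerate segment)."""


class DegenerateImageError(LaminafluctError):
    """The image has no usable structure (e.g. constant image fed to Otsu)."""


class RoleError(LaminafluctError):
    """A required channel role is missing or ambiguous."""


class ParameterError(LaminafluctError):
    """A numerical parameter violates a stability or validity constraint."""


class ContractError(LaminafluctError):
    """An interface contract between pipeline stages is violated."""
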