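"""Exception hierarchy for modewire."""


class ModewireError(Exception):
    """Base class for all modewire errors."""


class StructureError(ModewireError):
    """Malformed or empty structure input (no CA atoms, insertion codes, ...)."""


class DegenerateSuperpositionError(ModewireError):
    """Fewer than three corresponded points, or a collinear point set."""


class NetworkError(ModewireError):
    """Invalid elastic network (coincident nodes, bad cutoff, ...)."""


class ModeError(ModewireError):
    """Invalid mode request (empty subset, zero-length transition, ...)."""


class ConfigurationError(ModewireError):
    """Invalid pipeline or assembly configuration (missing segments, paths)."""
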