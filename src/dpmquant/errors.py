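"""Exception hierarchy shared by all stages."""


class DpmQuantError(ValueError):
    """Base class for all pipeline errors."""


class FormatError(DpmQuantError):
    """Malformed input table or record (missing column, bad mod string ...)."""


class DesignError(DpmQuantError):
    """Experimental design inconsistency (unknown channel, missing group ...)."""


class MappingError(DpmQuantError):
    """Peptide or modification could not be placed on a reference sequence."""


class ConfigError(DpmQuantError):
    """Invalid pipeline or simulation configuration."""
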