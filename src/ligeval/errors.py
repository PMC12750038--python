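"""Exception hierarchy for ligeval."""


class LigevalError(Exception):
    """Base class for all ligeval errors."""


class ParseError(LigevalError):
    """A structure or molecule file could not be parsed."""


class LigandMismatchError(LigevalError):
    """A ligand's connectivity graph does not match the declared SMILES."""


class UndefinedScoreError(LigevalError):
    """A metric is undefined for the given inputs (e.g. no reference contacts)."""


class SuperpositionError(LigevalError):
    """Too few corresponding points to define a binding-site superposition."""


class ConfigError(LigevalError):
    """Invalid run configuration."""
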