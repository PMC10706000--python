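"""Exception types shared across the package."""


class GraphGPTError(Exception):
    """Base class for package errors."""


class ParseError(GraphGPTError):
    """A SMILES string could not be parsed or sanitized."""


class TokenizationError(GraphGPTError):
    """A SMILES string contains a character outside the tokenizer alphabet."""


class ConfigurationError(GraphGPTError):
    """Invalid or inconsistent configuration (missing files, bad schema, ...)."""


class LengthError(GraphGPTError):
    """An encoded sequence exceeds the model's maximum length."""
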