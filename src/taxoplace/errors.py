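"""Exception hierarchy."""


class TaxoplaceError(Exception):
    """Base class for all taxoplace errors."""


class NewickParseError(TaxoplaceError):
    """Malformed Newick text (unbalanced parentheses, bad tokens, ...)."""


class FormatError(TaxoplaceError):
    """A structurally invalid input document (jplace, TSV, FASTA, mask)."""


class ValidationError(TaxoplaceError):
    """Structurally parseable input that violates a semantic contract."""
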