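"""Exception hierarchy for rcckit."""


class RCCError(Exception):
    """Base class for all rcckit errors."""


class PDBInputError(RCCError):
    """The input file could not be read or parsed as PDB."""


class EmptyStructureError(RCCError):
    """Parsing succeeded but no amino-acid residues were found."""


class UnknownChainError(RCCError, KeyError):
    """A requested chain id does not exist in the structure."""


class GraphSizeError(RCCError):
    """A brute-force routine was asked to process a graph beyond its size limit."""


class GenerationError(RCCError):
    """A synthetic-structure generator failed to satisfy its constraints."""


class BatchRunError(RCCError):
    """A batch run could not produce any result (e.g., every input failed)."""
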