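"""Exception hierarchy shared across the package."""


class SeqSubtypeError(Exception):
    """Base class for all package errors."""


class FastaFormatError(SeqSubtypeError):
    """Malformed FASTA input (empty sequence, missing header, ...)."""


class InvalidResidueError(SeqSubtypeError):
    """A sequence contains characters outside the 20 standard residues."""


class LengthError(SeqSubtypeError):
    """A sequence is too short for the requested descriptor."""


class DegenerateClusteringError(SeqSubtypeError):
    """A clustering is degenerate (coincident centroids, empty map, ...)."""
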