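"""Exception hierarchy.

All errors raised by pepmap derive from :class:`PepmapError` so callers (and the
CLI) can distinguish input/format problems from programming errors.
"""


class PepmapError(Exception):
    """Base class for all pepmap errors."""


class GtfParseError(PepmapError):
    """Malformed GTF input (wrong column count, missing required attribute)."""


class AnnotationError(PepmapError):
    """Inconsistent transcript structure (overlapping CDS, mixed strands)."""


class CoordinateError(PepmapError):
    """Residue/nucleotide range outside a transcript's coding region."""


class FastaError(PepmapError):
    """Protein FASTA problems (duplicate keys, unusable records)."""


class PeptideTableError(PepmapError):
    """Malformed 4-column peptide table or MaxQuant peptides.txt."""


class ModifiedSequenceError(PeptideTableError):
    """Malformed inline PTM annotation in a peptide sequence."""


class SearchInputError(PepmapError):
    """Invalid peptide or parameters passed to the mismatch search."""


class ConfigurationError(PepmapError):
    """Run-level configuration problems, e.g. FASTA/GTF identifier join failure."""


class FixtureError(PepmapError):
    """Infeasible synthetic fixture specification."""


class TrackHubError(PepmapError):
    """Track-hub generation problems (no BED input, bad assembly name)."""
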