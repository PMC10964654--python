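"""Exception hierarchy."""


class HippoError(Exception):
    """Base class for all package errors."""


class TypingTableError(HippoError):
    """Invalid atom->bead typing table (bad index, bad counts, bad schema)."""


class UnknownResidueError(TypingTableError):
    """Residue name not covered by the typing table."""


class StructureError(HippoError):
    """Invalid or empty coarse-grained structure."""


class PoolError(HippoError):
    """Invalid pose pool (mismatched beads, missing labels or ranks)."""


class PotentialError(HippoError):
    """Distance-array / histogram derivation failure."""


class ScoringError(HippoError):
    """Scoring-time failure (e.g. typing-table mismatch)."""


class GeneratorError(HippoError):
    """Infeasible synthetic-pool configuration."""
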