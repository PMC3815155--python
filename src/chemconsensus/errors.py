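"""Exception hierarchy for the curation pipeline.

The pipeline distinguishes three failure families so callers can degrade
gracefully: a *source* failing (network/disk), a *record* being absent or
unparseable, and a *structure* failing standardization.  Source failures
never abort a multi-source run; they are recorded and the source simply
contributes no vote mass.
"""

from __future__ import annotations


class ChemConsensusError(Exception):
    """Base class for all package errors."""


class SourceError(ChemConsensusError):
    """A record source was unreachable or unreadable."""

    def __init__(self, source_name: str, message: str = ""):
        self.source_name = source_name
        super().__init__(message or f"source {source_name!r} is unavailable")


class UnknownSourceError(ChemConsensusError):
    """A source name is not registered in the registry."""


class RecordNotFoundError(ChemConsensusError):
    """A record id does not exist in the named source."""

    def __init__(self, source_name: str, record_id: str):
        self.source_name = source_name
        self.record_id = record_id
        super().__init__(f"record {record_id!r} not found in source {source_name!r}")


class StructureParseError(ChemConsensusError):
    """A stored structure (molfile or SMILES) failed to parse.

    Carries the coordinates of the offending record when known.
    """

    def __init__(self, message: str, source_name: str | None = None,
                 record_id: str | None = None):
        self.source_name = source_name
        self.record_id = record_id
        if source_name is not None:
            message = f"{message} [source={source_name!r} id={record_id!r}]"
        super().__init__(message)


class NoApiFragmentError(ChemConsensusError):
    """Every fragment of a structure is on the salt/solvent exclusion list."""


class StandardizationError(ChemConsensusError):
    """Structure standardization failed (e.g. valence violation)."""

    def __init__(self, message: str, provenance=()):
        self.provenance = tuple(provenance)
        super().__init__(message)


class FixtureFormatError(ChemConsensusError):
    """A fixture file is malformed; names the file and line."""

    def __init__(self, path, line_no: int, message: str):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class DuplicateSourceError(ChemConsensusError):
    """Two reference hits claim the same source in one tally."""


class CorruptionNotApplicableError(ChemConsensusError):
    """A corruption mode cannot be applied to this molecule."""
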