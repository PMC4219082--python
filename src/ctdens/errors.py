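"""Exception hierarchy for ctdens.

Segmentation failures carry the pipeline stage that produced them so a
series run can report which slice and stage went wrong.
"""


class CTDensError(Exception):
    """Base class for all ctdens errors."""


class FixtureFormatError(CTDensError):
    """Unreadable or inconsistent slice files (mixed grid sizes, bad manifest)."""


class InvalidMetadataError(CTDensError):
    """Invalid acquisition metadata, e.g. a zero rescale slope."""


class SegmentationError(CTDensError):
    """Base for artifact-elimination failures."""

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        if stage is not None:
            message = f"[stage={stage}] {message}"
        super().__init__(message)


class NoCraniumError(SegmentationError):
    """No cranial bone found where the operation requires one."""


class UnsealableCraniumError(SegmentationError):
    """A defect and its mirror image are both open; the shell cannot be closed."""


class OpenShellError(SegmentationError):
    """Interior extraction attempted on a shell that is not sealed."""


class EmptyRegionError(SegmentationError):
    """Zero retained intracranial pixels; the slice is excluded from distributions."""


class LevelError(CTDensError):
    """A distribution of the wrong level (slice/series/group) was supplied."""


class DegenerateSampleError(CTDensError):
    """A statistical test received a constant or too-small sample."""
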