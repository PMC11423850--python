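"""Packaged data files."""

from __future__ import annotations

from importlib import resources

from ..relevance_affinity import ExclusionList


def default_exclusion_list() -> ExclusionList:
    """The packaged crystallization-additive exclusion list.

    A stand-in shipped with the toolkit; any curated one-ID-per-line list
    can replace it via ``PipelineConfig.exclusion_path``.
    """
    ref = resources.files(__package__) / "exclusion_additives.txt"
    with resources.as_file(ref) as path:
        return ExclusionList.from_file(path)
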