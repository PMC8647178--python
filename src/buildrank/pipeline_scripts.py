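"""Ready-to-run shell-script templates for each pipeline variant.

The recommender's output is only useful if the user can actually run the
suggested variant, so every registry entry can be rendered as a POSIX shell
script: optional Parrot density modification of the starting map, the first
pipeline, and — for pairs — the second pipeline seeded with the first one's
output model.  The templates carry placeholder invocations (pipeline
command-line syntax varies by version and the binaries are not dependencies
of this package); they are emitted as editable text, never executed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .variants import PipelineVariant

__all__ = ["ScriptConfig", "generate_script", "write_scripts"]


@dataclass(frozen=True)
class ScriptConfig:
    """User-supplied paths substituted into the script templates."""

    mtz_path: str = "input.mtz"
    seq_path: str = "input.seq"
    workdir: str = "build"
    extra_env: tuple[tuple[str, str], ...] = field(default_factory=tuple)


# command template per pipeline: {mtz} {seq} {workdir} {model_in_flag} {out}
_COMMANDS = {
    "ARP/wARP": "auto_tracing.sh datafile {mtz} seqin {seq}{model_in} modelout {out}",
    "Buccaneer": "cbuccaneer -mtzin {mtz} -seqin {seq}{model_in} -pdbout {out}",
    "Phenix AutoBuild": "phenix.autobuild data={mtz} seq_file={seq}{model_in} pdb_out={out}",
    "SHELXE": "shelxe_wrapper.sh mtzin {mtz} seqin {seq}{model_in} pdbout {out}",
}

_MODEL_IN_FLAG = {
    "ARP/wARP": " modelin {path}",
    "Buccaneer": " -pdbin-mr {path}",
    "Phenix AutoBuild": " input_model={path}",
    "SHELXE": " pdbin {path}",
}

_STAGE_SLUG = {
    "ARP/wARP": "arpwarp",
    "Buccaneer": "buccaneer",
    "Phenix AutoBuild": "autobuild",
    "SHELXE": "shelxe",
}


def generate_script(variant: PipelineVariant, config: ScriptConfig) -> str:
    """Render the shell script for one variant; deterministic per input."""
    lines = [
        "#!/bin/sh",
        "# pipeline variant: " + variant.variant_id,
        "set -e",
        "",
        f'WORKDIR="{config.workdir}"',
        'mkdir -p "$WORKDIR"',
    ]
    for key, value in config.extra_env:
        lines.append(f'export {key}="{value}"')
    lines.append("")
    mtz = config.mtz_path
    if variant.parrot_preconditioned:
        modified = f"$WORKDIR/parrot-modified.mtz"
        lines += [
            "# density modification of the starting map",
            f'cparrot -mtzin "{config.mtz_path}" -mtzout "{modified}"',
            "",
        ]
        mtz = modified
    previous_model: str | None = None
    for stage in variant.stages:
        out = f"$WORKDIR/{_STAGE_SLUG[stage]}.pdb"
        model_in = (
            _MODEL_IN_FLAG[stage].format(path=previous_model) if previous_model else ""
        )
        lines += [
            f"# {stage}",
            _COMMANDS[stage].format(mtz=f'"{mtz}"', seq=f'"{config.seq_path}"',
                                    model_in=model_in, out=f'"{out}"'),
            "",
        ]
        previous_model = out
    lines.append(f'echo "final model: {previous_model}"')
    return "\n".join(lines) + "\n"


def write_scripts(
    registry: Sequence[PipelineVariant], config: ScriptConfig, outdir: str | Path
) -> list[Path]:
    """One script file per registry variant; names are the variant ids."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    seen: set[str] = set()
    for variant in registry:
        if variant.variant_id in seen:
            raise ValueError(f"duplicate variant_id {variant.variant_id!r}")
        seen.add(variant.variant_id)
        path = outdir / f"{variant.variant_id}.sh"
        path.write_text(generate_script(variant, config))
        paths.append(path)
    return paths
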