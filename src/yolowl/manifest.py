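"""Layer manifest: the declarative architecture description.

The network is built from a YAML manifest whose rows mirror the published
layer table (index, input source, repeats, module name, arguments,
expected parameter count). The manifest is data, not code: alternative
channel widths — including the stride-32 channel compression already baked
into the default rows — are a manifest edit.

The shipped default manifest (``yolowl/data/yolo_wl.yaml``) transcribes
the published table verbatim. Its row 5 prints 1,048 parameters where the
gcd-grouping construction gives 1,408; the printed per-row sum differs
from the printed total by exactly 360 = 1,408 − 1,048, identifying the
printed row value as a transposition typo. The row therefore carries a
``corrected_params`` field and the audit reports the reconciliation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .msddsc import MSDDSCConfig

__all__ = [
    "KNOWN_MODULES",
    "LayerSpec",
    "ModelManifest",
    "parse_manifest",
    "serialize_manifest",
    "load_default_manifest",
    "scale_manifest",
]

KNOWN_MODULES = frozenset({
    "GCBS", "C2f-MSDDSC", "C2f", "SPPF", "SPFF", "Upsample",
    "SGF-2", "SGF-3", "MLKSA", "Conv", "Detect",
})


@dataclass(frozen=True)
class LayerSpec:
    index: int
    sources: tuple          # one or more earlier row indices; -1 = previous
    repeats: int
    module: str
    args: tuple
    expected_params: int | None = None
    corrected_params: int | None = None
    note: str | None = None

    @property
    def audit_target(self) -> int | None:
        """The count the built layer must match (typo-corrected if flagged)."""
        return self.corrected_params if self.corrected_params is not None \
            else self.expected_params

    def resolve_sources(self) -> tuple:
        return tuple(self.index - 1 if s == -1 else s for s in self.sources)


@dataclass
class ModelManifest:
    name: str
    num_classes: int
    reference_input: int
    rows: list
    summary: dict = field(default_factory=dict)
    msddsc: MSDDSCConfig = field(default_factory=MSDDSCConfig)

    def validate(self) -> None:
        for i, row in enumerate(self.rows):
            if row.index != i:
                raise ValueError(f"row indices not contiguous at {row.index}")
            if row.module not in KNOWN_MODULES:
                raise ValueError(f"unknown module {row.module!r} at row {row.index}")
            if i == 0:
                if row.sources != (-1,):
                    raise ValueError("row 0 must read the model input (from: -1)")
                continue
            for s in row.resolve_sources():
                if not 0 <= s < row.index:
                    raise ValueError(
                        f"dangling reference {s} at row {row.index}")

    def expected_total(self) -> int:
        """Sum of per-row audit targets (row-5 typo corrected)."""
        return sum(r.audit_target for r in self.rows if r.audit_target is not None)

    def static_consistency(self) -> bool:
        """Per-row sum (corrected) equals the printed whole-model total."""
        return self.expected_total() == self.summary.get("total_params")

    def digest(self) -> str:
        return hashlib.sha256(serialize_manifest(self).encode()).hexdigest()[:16]


def _parse_row(d: dict) -> LayerSpec:
    src = d["from"]
    sources = tuple(src) if isinstance(src, (list, tuple)) else (src,)
    return LayerSpec(
        index=int(d["index"]), sources=sources, repeats=int(d.get("repeats", 1)),
        module=str(d["module"]), args=tuple(d.get("args", ())),
        expected_params=d.get("expected_params"),
        corrected_params=d.get("corrected_params"), note=d.get("note"))


def parse_manifest(text: str) -> ModelManifest:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"manifest syntax error: {exc}") from exc
    if not isinstance(doc, dict) or "layers" not in doc:
        raise ValueError("manifest must be a mapping with a 'layers' section")
    ms = doc.get("msddsc", {})
    if "rates" in ms:
        ms = dict(ms, rates=tuple(ms["rates"]))
    m = ModelManifest(
        name=doc.get("name", "model"),
        num_classes=int(doc.get("num_classes", 6)),
        reference_input=int(doc.get("reference_input", 640)),
        rows=[_parse_row(r) for r in doc["layers"]],
        summary=dict(doc.get("summary", {})),
        msddsc=MSDDSCConfig(**ms),
    )
    m.validate()
    return m


def serialize_manifest(m: ModelManifest) -> str:
    ms = {
        "e": m.msddsc.e, "rates": list(m.msddsc.rates), "kernel": m.msddsc.kernel,
        "expand_ratio": m.msddsc.expand_ratio, "pw_ratio": m.msddsc.pw_ratio,
        "fuse_kernel": m.msddsc.fuse_kernel, "fuse_ratio": m.msddsc.fuse_ratio,
        "compress_bn": m.msddsc.compress_bn, "branch_bn": m.msddsc.branch_bn,
        "pw_bn": m.msddsc.pw_bn, "fuse_bn": m.msddsc.fuse_bn,
        "fuse_bias": m.msddsc.fuse_bias, "gate_kernel": m.msddsc.gate_kernel,
        "gate_bias": m.msddsc.gate_bias, "residual": m.msddsc.residual,
        "residual_projection": m.msddsc.residual_projection,
    }
    rows = []
    for r in m.rows:
        d = {"index": r.index,
             "from": list(r.sources) if len(r.sources) > 1 else r.sources[0],
             "repeats": r.repeats, "module": r.module, "args": list(r.args)}
        if r.expected_params is not None:
            d["expected_params"] = r.expected_params
        if r.corrected_params is not None:
            d["corrected_params"] = r.corrected_params
        if r.note is not None:
            d["note"] = r.note
        rows.append(d)
    doc = {"name": m.name, "num_classes": m.num_classes,
           "reference_input": m.reference_input, "summary": m.summary,
           "msddsc": ms, "layers": rows}
    return yaml.safe_dump(doc, sort_keys=False)


def load_default_manifest() -> ModelManifest:
    text = resources.files("yolowl").joinpath("data/yolo_wl.yaml").read_text()
    return parse_manifest(text)


def _scale(c: int, mult: float) -> int:
    return max(2, int(round(c * mult / 2)) * 2)


def scale_manifest(m: ModelManifest, width_mult: float) -> ModelManifest:
    """Width-scaled variant (channels rounded to even); used for small
    smoke-training models. Expected counts no longer apply and are dropped."""
    rows = []
    for r in m.rows:
        args = list(r.args)
        if r.module in ("GCBS", "Conv"):
            args[0] = _scale(args[0], width_mult) if r.index else args[0]
            args[1] = _scale(args[1], width_mult)
        elif r.module in ("C2f", "C2f-MSDDSC", "SPPF", "SPFF"):
            args[0] = _scale(args[0], width_mult)
            args[1] = _scale(args[1], width_mult)
        elif r.module == "MLKSA":
            args[0] = _scale(args[0], width_mult)
        elif r.module == "Detect":
            args[1] = [_scale(c, width_mult) for c in args[1]]
        rows.append(LayerSpec(r.index, r.sources, r.repeats, r.module,
                              tuple(args), None, None, None))
    return ModelManifest(name=f"{m.name}-w{width_mult}",
                         num_classes=m.num_classes,
                         reference_input=m.reference_input,
                         rows=rows, summary={}, msddsc=m.msddsc)
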