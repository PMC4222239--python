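"""XML storage container: the codec's self-describing metadata record.

The container binds everything a decoder needs and nothing more: message
identity (name, raw length, CRC-32), compression settings, fragment
layout (count, header length, per-fragment pad bits) and the LDPC code
parameters (n, k, column weight, construction seed — the matrix itself is
reconstructed deterministically from these).  The schema is versioned and
deliberately extensible: unknown child elements are preserved verbatim on
a read/write round trip so third parties can attach their own metadata.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

__all__ = ["StorageContainer", "ContainerError", "read_container", "write_container"]

FORMAT_VERSION = "1"
_ROOT_TAG = "dnastore"
_KNOWN_TAGS = {"message", "compression", "layout", "code"}


class ContainerError(ValueError):
    """Malformed or unsupported container document."""


@dataclass
class StorageContainer:
    name: str
    raw_len: int
    crc32: int
    compressed_len: int
    preset: int
    n_fragments: int
    code_n: int
    code_k: int
    code_col_weight: int
    code_seed: int
    header_len: int
    pad_lens: list[int]
    compression_alg: str = "lzma"
    compression_format: str = "alone"
    version: str = FORMAT_VERSION
    extra_elements: list = field(default_factory=list, repr=False)

    def to_xml(self) -> ET.Element:
        root = ET.Element(_ROOT_TAG, {"version": self.version})
        ET.SubElement(root, "message", {
            "name": self.name,
            "raw_length": str(self.raw_len),
            "crc32": f"{self.crc32:08x}",
            "compressed_length": str(self.compressed_len),
        })
        ET.SubElement(root, "compression", {
            "algorithm": self.compression_alg,
            "format": self.compression_format,
            "preset": str(self.preset),
        })
        layout = ET.SubElement(root, "layout", {
            "n_fragments": str(self.n_fragments),
            "header_length": str(self.header_len),
        })
        for a, pad in enumerate(self.pad_lens):
            ET.SubElement(layout, "fragment", {"address": str(a), "pad_len": str(pad)})
        ET.SubElement(root, "code", {
            "n": str(self.code_n), "k": str(self.code_k),
            "col_weight": str(self.code_col_weight), "seed": str(self.code_seed),
        })
        for el in self.extra_elements:
            root.append(copy.deepcopy(el))
        return root

    @classmethod
    def from_xml(cls, root: ET.Element) -> "StorageContainer":
        if root.tag != _ROOT_TAG:
            raise ContainerError(f"unexpected root element <{root.tag}>")
        version = root.get("version")
        if version != FORMAT_VERSION:
            raise ContainerError(f"unsupported container version {version!r}")

        def need(parent: ET.Element, tag: str) -> ET.Element:
            el = parent.find(tag)
            if el is None:
                raise ContainerError(f"missing mandatory element <{tag}>")
            return el

        def attr(el: ET.Element, name: str) -> str:
            v = el.get(name)
            if v is None:
                raise ContainerError(
                    f"missing attribute {name!r} on element <{el.tag}>")
            return v

        msg = need(root, "message")
        comp = need(root, "compression")
        layout = need(root, "layout")
        code = need(root, "code")
        n_fragments = int(attr(layout, "n_fragments"))
        pads = {int(attr(f, "address")): int(attr(f, "pad_len"))
                for f in layout.findall("fragment")}
        if set(pads) != set(range(n_fragments)):
            raise ContainerError("layout fragments do not cover all addresses")
        extra = [copy.deepcopy(el) for el in root if el.tag not in _KNOWN_TAGS]
        return cls(
            name=attr(msg, "name"),
            raw_len=int(attr(msg, "raw_length")),
            crc32=int(attr(msg, "crc32"), 16),
            compressed_len=int(attr(msg, "compressed_length")),
            compression_alg=attr(comp, "algorithm"),
            compression_format=attr(comp, "format"),
            preset=int(attr(comp, "preset")),
            n_fragments=n_fragments,
            header_len=int(attr(layout, "header_length")),
            pad_lens=[pads[a] for a in range(n_fragments)],
            code_n=int(attr(code, "n")),
            code_k=int(attr(code, "k")),
            code_col_weight=int(attr(code, "col_weight")),
            code_seed=int(attr(code, "seed")),
            version=version,
            extra_elements=extra,
        )


def write_container(container: StorageContainer, path) -> None:
    tree = ET.ElementTree(container.to_xml())
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_container(path) -> StorageContainer:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise ContainerError(f"not a well-formed XML container: {e}") from e
    return StorageContainer.from_xml(root)
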