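"""Minimal HML messages: a stripped-down profile of the histoimmunogenetics
markup language for exchanging HLA typing results.

The profile keeps the elements a receiving registry or transplant center
actually needs to interpret a typing: a header (message id, creation
timestamp, reporting center), one or more samples with registry-specific
identifier properties (``lab-ref`` typing center, ``tc-ref`` transplant
center, ``patient-ref`` patient identifier), and per-gene-family allele
assignments that bind a GL String to the database release it was called
against.  An optional machine-readable typing-method block and an opaque
consensus-sequence payload complete the profile.

XML is the primary wire format; an equivalent JSON serialization mirrors the
model one-to-one so that converting between the two is lossless — the
structure and semantics do not change with the container syntax.  Unknown
elements are preserved verbatim in per-container extras bags, so documents
richer than the minimal profile survive a round trip untouched.
"""

from __future__ import annotations

import copy
import io
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Header",
    "TypingMethod",
    "AlleleAssignment",
    "Typing",
    "Sample",
    "HmlMessage",
    "HmlError",
    "HmlParseError",
    "HmlStructureError",
    "HmlJsonError",
    "HmlSerializationError",
    "read_hml_xml",
    "write_hml_xml",
    "to_json",
    "from_json",
    "export_consensus_fasta",
]

# Typographic glyphs that appear in typeset renditions of HML examples;
# normalized to ASCII on read because they are typesetting artifacts.
_GLYPH_MAP = str.maketrans(
    {
        "‐": "-",  # hyphen
        "‑": "-",  # non-breaking hyphen
        "‒": "-",
        "–": "-",  # en dash
        "—": "-",  # em dash
        "‘": "'",
        "’": "'",
        "“": '"',
        "”": '"',
    }
)

_KNOWN_HML_CHILDREN = {"hmlid", "reporting-center", "sample"}
_KNOWN_SAMPLE_CHILDREN = {"property", "typing"}
_KNOWN_TYPING_CHILDREN = {"allele-assignment", "typing-method", "consensus-sequence"}


class HmlError(ValueError):
    pass


class HmlParseError(HmlError):
    """Input is not well-formed XML."""


class HmlStructureError(HmlError):
    """Well-formed XML violating the message profile; carries element paths."""


class HmlJsonError(HmlError):
    """JSON input missing required paths."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("missing required paths: " + ", ".join(missing))


class HmlSerializationError(HmlError):
    """Refusal to serialize an invariant-violating message."""


@dataclass
class Header:
    message_id: str
    created: str = ""
    reporting_center: str = ""


@dataclass
class TypingMethod:
    """Machine-readable description of how the typing was performed."""

    description: str
    platform: str = ""
    exons_targeted: list[int] = field(default_factory=list)
    software: str = ""
    software_version: str = ""


@dataclass
class AlleleAssignment:
    """A GL String bound to the database release it was called against."""

    allele_db: str
    allele_version: str
    date: str
    glstring: str


@dataclass
class Typing:
    gene_family: str
    assignment: AlleleAssignment
    method: Optional[TypingMethod] = None
    consensus: Optional[str] = None
    extras: list[str] = field(default_factory=list)


@dataclass
class Sample:
    sample_id: str
    properties: dict[str, str] = field(default_factory=dict)
    typings: list[Typing] = field(default_factory=list)
    extras: list[str] = field(default_factory=list)


@dataclass
class HmlMessage:
    header: Header
    samples: list[Sample]
    version: str = "1.0.1"
    extras: list[str] = field(default_factory=list)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _canonical_fragment(elem: ET.Element) -> str:
    """Stable serialization of an unknown element: namespace-agnostic tags,
    no inter-element whitespace, attribute order as parsed."""
    node = copy.deepcopy(elem)
    for e in node.iter():
        e.tag = _local(e.tag)
        if e.tail is not None:
            e.tail = None
        if e.text is not None and not e.text.strip():
            e.text = None
    return ET.tostring(node, encoding="unicode")


def read_hml_xml(document: str) -> HmlMessage:
    """Parse a minimal-profile HML document into the message model.

    Documents are accepted with or without an XML namespace.  Typographic
    hyphens and quotes are normalized to ASCII.  Unknown elements land in the
    extras bag of their container and survive every round trip verbatim.
    """
    text = document.translate(_GLYPH_MAP)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise HmlParseError(f"document is not well-formed XML: {exc}") from exc
    if _local(root.tag) != "hml":
        raise HmlStructureError(f"root element is <{_local(root.tag)}>, expected <hml>")

    header = Header(
        message_id="",
        created=root.get("created", ""),
    )
    msg = HmlMessage(header=header, samples=[], version=root.get("version", "1.0.1"))

    for child in root:
        tag = _local(child.tag)
        if tag == "hmlid":
            header.message_id = child.get("extension", child.get("root", ""))
        elif tag == "reporting-center":
            header.reporting_center = child.get("reporting-center-id", "")
        elif tag == "sample":
            msg.samples.append(_read_sample(child))
        else:
            msg.extras.append(_canonical_fragment(child))

    if not msg.samples:
        raise HmlStructureError("missing sample section at hml")
    if not header.message_id:
        raise HmlStructureError("missing or empty message id at hml/hmlid")
    return msg


def _read_sample(elem: ET.Element) -> Sample:
    sample_id = elem.get("id", "")
    if not sample_id:
        raise HmlStructureError("sample without an id attribute at hml/sample")
    sample = Sample(sample_id=sample_id)
    for child in elem:
        tag = _local(child.tag)
        if tag == "property":
            name = child.get("name", "")
            if not name:
                raise HmlStructureError(
                    f"property without a name at hml/sample[{sample_id}]"
                )
            if name in sample.properties:
                raise HmlStructureError(
                    f"duplicate property key at hml/sample[{sample_id}]/property[{name}]"
                )
            sample.properties[name] = child.get("value", "")
        elif tag == "typing":
            sample.typings.append(_read_typing(child, sample_id))
        else:
            sample.extras.append(_canonical_fragment(child))
    return sample


def _read_typing(elem: ET.Element, sample_id: str) -> Typing:
    path = f"hml/sample[{sample_id}]/typing"
    assignment: Optional[AlleleAssignment] = None
    method: Optional[TypingMethod] = None
    consensus: Optional[str] = None
    extras: list[str] = []
    for child in elem:
        tag = _local(child.tag)
        if tag == "allele-assignment":
            gl = child.find("glstring")
            if gl is None:
                gl = next(
                    (c for c in child if _local(c.tag) == "glstring"), None
                )
            assignment = AlleleAssignment(
                allele_db=child.get("allele-db", ""),
                allele_version=child.get("allele-version", ""),
                date=child.get("date", ""),
                glstring=(gl.text or "").strip() if gl is not None else "",
            )
        elif tag == "typing-method":
            fields = {_local(c.tag): (c.text or "").strip() for c in child}
            exons = [
                int(x) for x in fields.get("exons-targeted", "").split(",") if x.strip()
            ]
            method = TypingMethod(
                description=fields.get("description", ""),
                platform=fields.get("platform", ""),
                exons_targeted=exons,
                software=fields.get("software", ""),
                software_version=fields.get("software-version", ""),
            )
        elif tag == "consensus-sequence":
            consensus = (child.text or "").strip()
        else:
            extras.append(_canonical_fragment(child))
    if assignment is None:
        raise HmlStructureError(f"typing without allele-assignment at {path}")
    return Typing(
        gene_family=elem.get("gene-family", ""),
        assignment=assignment,
        method=method,
        consensus=consensus,
        extras=extras,
    )


def _check_serializable(msg: HmlMessage) -> None:
    if not msg.header.message_id:
        raise HmlSerializationError("refusing to serialize: empty message id")
    if not msg.samples:
        raise HmlSerializationError("refusing to serialize: empty samples list")
    for s in msg.samples:
        if not s.sample_id:
            raise HmlSerializationError("refusing to serialize: sample without id")


def write_hml_xml(msg: HmlMessage) -> str:
    """Deterministic XML serialization.

    Element order is fixed (header elements, then samples in input order,
    properties sorted by key), so the same message always produces the same
    bytes.  Extras bags are re-emitted verbatim in place.
    """
    _check_serializable(msg)
    root = ET.Element("hml", {"version": msg.version})
    if msg.header.created:
        root.set("created", msg.header.created)
    ET.SubElement(root, "hmlid", {"extension": msg.header.message_id})
    if msg.header.reporting_center:
        ET.SubElement(
            root, "reporting-center", {"reporting-center-id": msg.header.reporting_center}
        )
    for sample in msg.samples:
        s_el = ET.SubElement(root, "sample", {"id": sample.sample_id})
        for name in sorted(sample.properties):
            ET.SubElement(s_el, "property", {"name": name, "value": sample.properties[name]})
        for typing in sample.typings:
            t_el = ET.SubElement(s_el, "typing")
            if typing.gene_family:
                t_el.set("gene-family", typing.gene_family)
            a = typing.assignment
            a_el = ET.SubElement(t_el, "allele-assignment")
            if a.allele_db:
                a_el.set("allele-db", a.allele_db)
            if a.allele_version:
                a_el.set("allele-version", a.allele_version)
            if a.date:
                a_el.set("date", a.date)
            ET.SubElement(a_el, "glstring").text = a.glstring
            if typing.method is not None:
                m = typing.method
                m_el = ET.SubElement(t_el, "typing-method")
                ET.SubElement(m_el, "description").text = m.description
                if m.platform:
                    ET.SubElement(m_el, "platform").text = m.platform
                if m.exons_targeted:
                    ET.SubElement(m_el, "exons-targeted").text = ",".join(
                        str(x) for x in m.exons_targeted
                    )
                if m.software:
                    ET.SubElement(m_el, "software").text = m.software
                if m.software_version:
                    ET.SubElement(m_el, "software-version").text = m.software_version
            if typing.consensus is not None:
                ET.SubElement(t_el, "consensus-sequence").text = typing.consensus
            for extra in typing.extras:
                t_el.append(ET.fromstring(extra))
        for extra in sample.extras:
            s_el.append(ET.fromstring(extra))
    for extra in msg.extras:
        root.append(ET.fromstring(extra))

    ET.indent(root, space="  ")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    ) + "\n"


def _method_to_dict(m: TypingMethod) -> dict:
    return {
        "description": m.description,
        "platform": m.platform,
        "exons_targeted": list(m.exons_targeted),
        "software": m.software,
        "software_version": m.software_version,
    }


def to_json(msg: HmlMessage) -> str:
    """Canonical JSON mirror of the message: sorted keys, byte-stable."""
    _check_serializable(msg)
    doc = {
        "hml": {
            "version": msg.version,
            "message_id": msg.header.message_id,
            "created": msg.header.created,
            "reporting_center": msg.header.reporting_center,
            "extras": list(msg.extras),
            "samples": [
                {
                    "id": s.sample_id,
                    "properties": dict(s.properties),
                    "extras": list(s.extras),
                    "typings": [
                        {
                            "gene_family": t.gene_family,
                            "allele_assignment": {
                                "allele_db": t.assignment.allele_db,
                                "allele_version": t.assignment.allele_version,
                                "date": t.assignment.date,
                                "glstring": t.assignment.glstring,
                            },
                            "typing_method": (
                                _method_to_dict(t.method) if t.method else None
                            ),
                            "consensus_sequence": t.consensus,
                            "extras": list(t.extras),
                        }
                        for t in s.typings
                    ],
                }
                for s in msg.samples
            ],
        }
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def from_json(text: str) -> HmlMessage:
    """Parse the JSON mirror back into the model, collecting every missing
    required path into a single structured error."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise HmlParseError(f"document is not valid JSON: {exc}") from exc

    missing: list[str] = []

    def need(obj: dict, key: str, path: str):
        if not isinstance(obj, dict) or key not in obj:
            missing.append(f"{path}.{key}")
            return None
        return obj[key]

    hml = need(doc, "hml", "$")
    if hml is None:
        raise HmlJsonError(missing)
    message_id = need(hml, "message_id", "$.hml")
    samples_json = need(hml, "samples", "$.hml")

    samples: list[Sample] = []
    for i, s in enumerate(samples_json or []):
        spath = f"$.hml.samples[{i}]"
        sid = need(s, "id", spath)
        props = need(s, "properties", spath)
        typings: list[Typing] = []
        for j, t in enumerate(s.get("typings", []) if isinstance(s, dict) else []):
            tpath = f"{spath}.typings[{j}]"
            assignment = need(t, "allele_assignment", tpath)
            if assignment is not None:
                apath = f"{tpath}.allele_assignment"
                allele_db = need(assignment, "allele_db", apath)
                allele_version = need(assignment, "allele_version", apath)
                date = need(assignment, "date", apath)
                glstring = need(assignment, "glstring", apath)
            if assignment is None or missing:
                continue
            method_json = t.get("typing_method")
            method = (
                TypingMethod(
                    description=method_json.get("description", ""),
                    platform=method_json.get("platform", ""),
                    exons_targeted=[int(x) for x in method_json.get("exons_targeted", [])],
                    software=method_json.get("software", ""),
                    software_version=method_json.get("software_version", ""),
                )
                if isinstance(method_json, dict)
                else None
            )
            typings.append(
                Typing(
                    gene_family=t.get("gene_family", ""),
                    assignment=AlleleAssignment(
                        allele_db=allele_db,
                        allele_version=allele_version,
                        date=date,
                        glstring=glstring,
                    ),
                    method=method,
                    consensus=t.get("consensus_sequence"),
                    extras=list(t.get("extras", [])),
                )
            )
        samples.append(
            Sample(
                sample_id=sid or "",
                properties=dict(props or {}),
                typings=typings,
                extras=list(s.get("extras", [])) if isinstance(s, dict) else [],
            )
        )

    if missing:
        raise HmlJsonError(missing)

    return HmlMessage(
        header=Header(
            message_id=message_id or "",
            created=hml.get("created", ""),
            reporting_center=hml.get("reporting_center", ""),
        ),
        samples=samples,
        version=hml.get("version", "1.0.1"),
        extras=list(hml.get("extras", [])),
    )


def export_consensus_fasta(msg: HmlMessage, destination: Union[str, Path, io.TextIOBase]) -> int:
    """Write every consensus-sequence payload as FASTA; returns the record
    count.  Record ids are ``<sample_id>|<gene_family>``."""
    records = [
        SeqRecord(
            Seq(t.consensus),
            id=f"{s.sample_id}|{t.gene_family}",
            description="consensus sequence",
        )
        for s in msg.samples
        for t in s.typings
        if t.consensus
    ]
    if isinstance(destination, (str, Path)):
        with open(destination, "w") as handle:
            return SeqIO.write(records, handle, "fasta")
    return SeqIO.write(records, destination, "fasta")
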