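"""Reading and writing polygon annotations.

Two on-disk dialects are supported: the ASAP XML polygon format
(``Annotation`` elements with ``Coordinate`` children and a ``PartOfGroup``
attribute) and an equivalent GeoJSON ``FeatureCollection`` whose features
carry a ``classification`` property.  Coordinates are level-0 pixel
coordinates in both dialects.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

import numpy as np

from .core import Annotation, AnnotationSet

# Accepted group-name spellings -> canonical class.
_GROUP_ALIASES = {
    "tissue": "tissue",
    "background": "background",
    "edge": "edge",
    "edge artifacts": "edge",
    "edge_artifacts": "edge",
    "inner_artifact": "inner_artifact",
    "inner artifacts": "inner_artifact",
    "inner_artifacts": "inner_artifact",
    "artifacts": "inner_artifact",
}


def _canonical_label(name: str) -> str:
    try:
        return _GROUP_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown annotation group {name!r}") from None


def read_asap_xml(path) -> AnnotationSet:
    root = ET.parse(path).getroot()
    anns = []
    for node in root.iter("Annotation"):
        group = node.get("PartOfGroup") or node.get("Group") or ""
        coords = node.find("Coordinates")
        if coords is None:
            continue
        pts = sorted(
            (
                (int(c.get("Order", i)), float(c.get("X")), float(c.get("Y")))
                for i, c in enumerate(coords.findall("Coordinate"))
            ),
        )
        verts = np.array([(x, y) for _, x, y in pts], dtype=float)
        if len(verts) >= 3:
            anns.append(Annotation(verts, _canonical_label(group)))
    return AnnotationSet(anns)


def write_asap_xml(annotations: AnnotationSet, path):
    root = ET.Element("ASAP_Annotations")
    anns_el = ET.SubElement(root, "Annotations")
    groups = set()
    for i, ann in enumerate(annotations):
        groups.add(ann.label)
        # interior rings are written as separate polygons of the same group
        rings = [ann.exterior] + list(ann.interiors)
        for j, ring in enumerate(rings):
            label = ann.label if j == 0 else "background"
            groups.add(label)
            el = ET.SubElement(
                anns_el,
                "Annotation",
                Name=f"Annotation {i}" + ("" if j == 0 else f" hole {j}"),
                Type="Polygon",
                PartOfGroup=label,
                Color="#F4FA58",
            )
            coords = ET.SubElement(el, "Coordinates")
            for k, (x, y) in enumerate(ring):
                ET.SubElement(
                    coords, "Coordinate", Order=str(k), X=repr(float(x)), Y=repr(float(y))
                )
    groups_el = ET.SubElement(root, "AnnotationGroups")
    for g in sorted(groups):
        ET.SubElement(groups_el, "Group", Name=g, PartOfGroup="None", Color="#64FE2E")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_geojson(path) -> AnnotationSet:
    with open(path) as fh:
        doc = json.load(fh)
    anns = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        label = props.get("classification") or props.get("label") or props.get("name")
        geom = feat.get("geometry", {})
        polys = []
        if geom.get("type") == "Polygon":
            polys = [geom["coordinates"]]
        elif geom.get("type") == "MultiPolygon":
            polys = geom["coordinates"]
        for rings in polys:
            if not rings:
                continue
            exterior = np.asarray(rings[0], dtype=float)
            # GeoJSON closes rings by repeating the first vertex
            if len(exterior) > 1 and np.allclose(exterior[0], exterior[-1]):
                exterior = exterior[:-1]
            interiors = []
            for hole in rings[1:]:
                h = np.asarray(hole, dtype=float)
                if len(h) > 1 and np.allclose(h[0], h[-1]):
                    h = h[:-1]
                interiors.append(h)
            anns.append(Annotation(exterior, _canonical_label(label), interiors))
    return AnnotationSet(anns)


def write_geojson(annotations: AnnotationSet, path):
    feats = []
    for ann in annotations:
        rings = [np.vstack([r, r[:1]]).tolist() for r in [ann.exterior] + list(ann.interiors)]
        feats.append(
            {
                "type": "Feature",
                "properties": {"classification": ann.label},
                "geometry": {"type": "Polygon", "coordinates": rings},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_annotations(path) -> AnnotationSet:
    """Dispatch on file extension (.xml -> ASAP, .json/.geojson -> GeoJSON)."""
    p = str(path).lower()
    if p.endswith(".xml"):
        return read_asap_xml(path)
    if p.endswith((".json", ".geojson")):
        return read_geojson(path)
    raise ValueError(f"unrecognized annotation file type: {path}")
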