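"""Structural NeuroML v2 export of generated networks.

The export covers the declarative *structure* of a network — populations
with 3D soma locations, chemical projections with weights, electrical
projections for gap junctions, continuous projections for graded synapses,
and explicit inputs for the stimulus protocols — in the NeuroML v2
namespace.  The dynamics (LEMS component definitions) are not emitted; the
built-in simulator is the executable semantics, and the XML serves
interchange and visualisation.

Element ordering is deterministic, and :func:`read_neuroml_summary` parses
the structure back for round-trip checking.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .builder import NetworkModel

NEUROML_NS = "http://www.neuroml.org/schema/neuroml2"


def _fmt(x: float) -> str:
    return repr(float(x))


def network_to_element(net: NetworkModel) -> ET.Element:
    root = ET.Element("neuroml", {"xmlns": NEUROML_NS, "id": "nemasim_export"})
    level = net.parameter_set.level
    graded = net.parameter_set.uses_graded

    # pulse generators for the stimuli
    for k, st in enumerate(net.stimuli):
        attrs = {
            "id": f"input_{k}",
            "delay": f"{st.onset} ms",
            "duration": f"{st.pulse_duration} ms",
            "amplitude": f"{st.amplitude} pA",
        }
        if st.period is not None:
            # periodic trains are an extension over the plain pulseGenerator
            attrs["period"] = f"{st.period} ms"
        if st.n_pulses is not None:
            attrs["number"] = str(st.n_pulses)
        ET.SubElement(root, "pulseGenerator", attrs)

    network = ET.SubElement(root, "network", {"id": "network"})

    for cell in net.cells:
        component = f"{'muscle' if cell.is_muscle else 'neuron'}_{level}"
        pop = ET.SubElement(network, "population", {
            "id": cell.name, "component": component, "size": "1",
            "type": "populationList",
        })
        inst = ET.SubElement(pop, "instance", {"id": "0"})
        x, y, z = cell.position
        ET.SubElement(inst, "location", {"x": _fmt(x), "y": _fmt(y), "z": _fmt(z)})

    for k, syn in enumerate(net.synapses):
        pre_path = f"../{syn.pre}/0"
        post_path = f"../{syn.post}/0"
        if syn.kind == "gap":
            proj = ET.SubElement(network, "electricalProjection", {
                "id": f"gap_{k}", "presynapticPopulation": syn.pre,
                "postsynapticPopulation": syn.post,
            })
            ET.SubElement(proj, "electricalConnection", {
                "id": "0", "preCell": pre_path, "postCell": post_path,
                "synapse": "gap_junction", "weight": _fmt(syn.weight),
            })
        elif graded:
            proj = ET.SubElement(network, "continuousProjection", {
                "id": f"{syn.kind}_{k}", "presynapticPopulation": syn.pre,
                "postsynapticPopulation": syn.post,
            })
            ET.SubElement(proj, "continuousConnection", {
                "id": "0", "preCell": pre_path, "postCell": post_path,
                "preComponent": "silent", "postComponent": syn.kind,
                "weight": _fmt(syn.weight),
            })
        else:
            proj = ET.SubElement(network, "projection", {
                "id": f"{syn.kind}_{k}", "presynapticPopulation": syn.pre,
                "postsynapticPopulation": syn.post, "synapse": syn.kind,
            })
            ET.SubElement(proj, "connectionWD", {
                "id": "0", "preCellId": pre_path, "postCellId": post_path,
                "weight": _fmt(syn.weight), "delay": "0 ms",
            })

    for k, st in enumerate(net.stimuli):
        ET.SubElement(network, "explicitInput", {
            "target": f"{st.target}/0", "input": f"input_{k}",
        })
    return root


def write_neuroml_subset(net: NetworkModel, stream) -> None:
    """Serialise the structural NeuroML document (UTF-8 text, indented)."""
    root = network_to_element(net)
    ET.indent(root)
    text = ET.tostring(root, encoding="unicode", xml_declaration=False)
    stream.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    stream.write(text)
    stream.write("\n")


def read_neuroml_summary(stream) -> dict:
    """Parse an exported document back into a structural summary.

    Returns cell names with positions, synapse tuples
    ``(pre, post, kind, weight)`` and the stimulus count — everything needed
    to verify a structurally lossless round trip against the source network.
    """
    tree = ET.parse(stream)
    root = tree.getroot()
    ns = {"n": NEUROML_NS}
    network = root.find("n:network", ns)
    if network is None:
        raise ValueError("document has no network element")

    cells = {}
    for pop in network.findall("n:population", ns):
        loc = pop.find("n:instance/n:location", ns)
        pos = (float(loc.get("x")), float(loc.get("y")), float(loc.get("z"))) \
            if loc is not None else None
        cells[pop.get("id")] = pos

    synapses = []
    for proj in network.findall("n:projection", ns):
        for conn in proj.findall("n:connectionWD", ns):
            synapses.append((proj.get("presynapticPopulation"),
                             proj.get("postsynapticPopulation"),
                             proj.get("synapse"), float(conn.get("weight"))))
    for proj in network.findall("n:continuousProjection", ns):
        for conn in proj.findall("n:continuousConnection", ns):
            synapses.append((proj.get("presynapticPopulation"),
                             proj.get("postsynapticPopulation"),
                             conn.get("postComponent"), float(conn.get("weight"))))
    for proj in network.findall("n:electricalProjection", ns):
        for conn in proj.findall("n:electricalConnection", ns):
            synapses.append((proj.get("presynapticPopulation"),
                             proj.get("postsynapticPopulation"),
                             "gap", float(conn.get("weight"))))

    n_inputs = len(network.findall("n:explicitInput", ns))
    return {"cells": cells, "synapses": synapses, "n_inputs": n_inputs}
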