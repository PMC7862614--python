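"""Brute-force graph-isomorphism oracle for CGR motifs (test-only).

Independent of the package's canonicalization/hashing path: motifs are
translated to attributed networkx graphs and compared with VF2.
"""

import networkx as nx


def to_networkx(cgr):
    g = nx.Graph()
    for i, a in cgr.atoms.items():
        r, p = a.reactant_state, a.product_state
        g.add_node(
            i,
            st=(
                a.element,
                None if r is None else (r.charge, r.radical, r.aromatic),
                None if p is None else (p.charge, p.radical, p.aromatic),
            ),
        )
    for (i, j), orders in cgr.bonds.items():
        g.add_edge(i, j, bo=orders)
    return g


def isomorphic(cgr_a, cgr_b):
    return nx.is_isomorphic(
        to_networkx(cgr_a),
        to_networkx(cgr_b),
        node_match=lambda x, y: x["st"] == y["st"],
        edge_match=lambda x, y: x["bo"] == y["bo"],
    )


def motif_invariants(cgr):
    """Cheap isomorphism-necessary invariants used to prefilter pairs."""
    return (
        len(cgr.atoms),
        len(cgr.bonds),
        tuple(sorted(a.element for a in cgr.atoms.values())),
        tuple(sorted((a or ".", b or ".") for a, b in cgr.bonds.values())),
    )
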