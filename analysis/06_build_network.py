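"""Build the regulator interaction network over the flagged regulators.

Amalgamates motif sets to gene symbols, draws an edge A->B whenever B's
symbol is in A's target list, annotates nodes with their MRSS-correlation
sign category in the two subsets, and exports GraphML/SIF/TSV.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SIM_DIR  # noqa: E402

from regact.io_formats import extract_symbol, read_gmt  # noqa: E402
from regact.network import build_network, export_network, sign_category  # noqa: E402


def main() -> None:
    sets = read_gmt(SIM_DIR / "sets.gmt")
    rankings = {
        subset: pd.read_csv(
            RESULTS / f"ranking_{subset}.tsv", sep="\t", index_col=0
        )
        for subset in ("fibroproliferative", "inflammatory")
    }
    flagged = sorted(
        set().union(
            *(
                set(t.index[t["flag"] != "none"])
                for t in rankings.values()
            )
        )
    )
    annotations = {}
    for name in flagged:
        sym = extract_symbol(name)
        if sym is None:
            continue
        annotations[sym] = sign_category(
            float(rankings["fibroproliferative"].loc[name, "aggregate"])
            if name in rankings["fibroproliferative"].index
            else None,
            float(rankings["inflammatory"].loc[name, "aggregate"])
            if name in rankings["inflammatory"].index
            else None,
        )
    symbols = sorted(annotations)
    net = build_network(sets, symbols, annotations)
    export_network(net, "graphml", RESULTS / "network.graphml")
    export_network(net, "sif", RESULTS / "network.sif")
    export_network(net, "edge_tsv", RESULTS / "network_edges.tsv")
    degrees = {n: net.nodes[n]["degree"] for n in net.nodes}
    hub = max(degrees, key=degrees.get) if degrees else None
    print(
        f"network over {net.number_of_nodes()} regulators, "
        f"{net.number_of_edges()} directed edges "
        f"({sum(1 for e in net.edges if e[0] == e[1])} self-loops); "
        f"highest-degree node: {hub} (degree {degrees.get(hub)})"
    )


if __name__ == "__main__":
    main()
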