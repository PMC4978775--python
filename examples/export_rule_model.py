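"""Export the network as rule-based model text and round-trip it.

The text mirrors a BioNetGen model file: molecule types with site states,
seed species, and grounded bind/unbind/catalysis rules.  Re-parsing
reconstructs the exact species list.
"""

from lckphos import build_network, export_rules, parse_rules, table1_median

net = build_network()
text = export_rules(net, table1_median())
print("\n".join(text.splitlines()[:14]))
print(f"... ({len(text.splitlines())} lines total)\n")

net2, params = parse_rules(text)
print(f"round trip: {len(net.species)} species exported, "
      f"{len(net2.species)} reconstructed, "
      f"identical order: "
      f"{[s.label for s in net.species] == [s.label for s in net2.species]}")
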