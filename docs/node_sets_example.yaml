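# SYNTHETIC editable node-set stubs for alternative network analyses
# (salience, mirror-neuron, motor).  These coordinates are placeholders
# chosen only to be plausible, non-overlapping sphere centers on an
# MNI-like grid -- they are NOT meta-analytic coordinates.  Replace them
# with your own node definitions before scientific use, then load with
#
#   from betaconn.config import load_node_set
#   rois = load_node_set("my_nodes.yaml")
#
# The 14-node mentalizing + reward default ships inside the package
# (betaconn.networks.DEFAULT_ROIS) and needs no file.
- {name: dACC,          network: salience, x: 0,   y: 20,  z: 36, radius: 5}
- {name: L anterior insula, network: salience, x: -38, y: 16,  z: -2, radius: 5}
- {name: R anterior insula, network: salience, x: 38,  y: 16,  z: -2, radius: 5}
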