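# Conformational-state windows per protein, nm.
# ca: inter-site Calpha-Calpha distance range between the tagged residues
#     (68/138 for the monomeric proteins, 68/139 for the PaCDT trimer).
# gd: equivalent modelled Gd(III)-Gd(III) distance range.
AncCDT-1:
  closed:    {ca: [2.5, 2.9], gd: [2.9, 3.4]}
  open:      {ca: [3.2, 3.7], gd: [3.9, 4.9]}
  wide-open: {ca: [3.6, 4.2], gd: [4.1, 5.2]}
AncCDT-3:
  wide-open: {ca: [4.0, 4.8], gd: [5.0, 6.3]}
AncCDT-5:
  open:      {ca: [3.0, 3.4], gd: [3.4, 4.2]}
  wide-open: {ca: [3.6, 4.2], gd: [4.5, 5.4]}
PaCDT:
  closed:    {ca: [2.5, 3.0], gd: [3.5, 3.9]}
  open:      {ca: [3.2, 3.8], gd: [4.0, 4.5]}
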