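# Default domain partition for T. litoralis ADP-dependent glucokinase,
# chain A, author residue numbering.  The small (lid) domain is the
# five-beta-strand/four-helix insertion in the large Rossmann-core domain;
# residues in the short hinge segments (42-43, 206-207) are left unassigned.
large = A:1-41, A:208-465
small = A:44-205
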