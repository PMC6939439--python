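# Deposited reference coordinates

Two acceptance checks validate the C-beta-deviation construction against
deposited PDB entries.  No copy of the archive files ships with this
package; to run those checks, download the entries and place them here:

    1bkr.pdb   (calponin homology domain, 1.1 A)   -> Thr101 Cbd ~ 0.63 A
    1nls.pdb   (concanavalin A, 0.94 A)            -> Thr196 Cbd ~ 0.88 A,
                                                      Ser215 CB A/B 0.49 A apart

e.g. from https://files.rcsb.org/download/1BKR.pdb .  Without the files the
two tests fail with an explanatory message.
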