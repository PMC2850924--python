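accession	class	residues
SYNBACA1	A	GRCMSIEQPIVMKCLPFGLKNCIIPETRILSYTTLYESTLSSFTLIYSSSPQSTGQILENFYPINRNEAPVKRAGAEEDLSSATIKPPFMIARLASARQLVRSLLLCAGAVDRLKKDVIDPPHMKSSTAAYMVRLILSAAY
SYNBACA2	A	NQVLLSIRIASMLKDECLGTDSHDKVATPKTVGEWIVRCEIVDTLQPHNYVATPRRLSSVPPYSMDPTDDRSAATEVQPGLRSGELSLVVFVYLAMVYRKCDAEIFIQSNNTMGADEAHPYFATVFYFQINFYSSVTSA
SYNBACB1	B	DIQEDTKTIRMAVYGYQGIAPRMPFSPCTQFHEAIEDETLSLYRVPVDYLCASYCAACSAASVILIEDRLRLLLNNMKLLEIMLDNITYVVQDLEVFMDNREQNNMQSQADHYAMAELKYKLGQFTRILGTISNRLFKANG
SYNBACB2	B	EVTIMARLMGTAFLCCRADFVDAYANETVGAVGSLLIGLLIEAYRLLANQGVDSGSLEGSAHSLAEDFEPSFGLERKRQHGSQLLFENIAYVLQAPVSQDVDTKGTKVSLSWVTLKIQWGT
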