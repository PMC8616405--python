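>Ubx_synthetic synthetic stand-in Hox protein
MTIVIREHCVFHIGKLDSKEPPSYFYYVDGTVLGSLGVVEGDYEINYFFCTVCSPARITV
NRPNLETGALQLQRKASAPTIHKRFQLCAYEDKPLCENAEEHSDQCYYEGLPQPTNADEF
TSHIRTVDTFEPADLSKYRDSNRSKIKPFAEILAHRVKQEAKDDSDIFGCVPFLICTGFE
TQKDEEHNQCRCIAFTQSAFLKHVLLPHLLETPAAKLLQEIFHLLDGINKDSGAESCTCV
TNHKPDETSDFSRIVTNKIHKQRSVSQPSPCAYYKDCGADECKISCYPSFLGNQRVEELG
CQDKPCPKVKKNRIIDLERQCRQAPKSRARKATNRDVRRKCYTKFE
>AbdA_synthetic synthetic stand-in Hox protein
MAEFLEICSDDAFSIAYAFQPPSYKPRDDGGSIYPDKACFTSYNVGISAALLASPARFQH
RIHLRTKYDFFEIYFNRKASAPGVSYESFRVNHDRSDYGVHVHAHYEGLGSEQEVEPDSS
FQLQLHINCRADKGPADLSKHIENAQRIHCHEAANNNAFFIRNTHRNRRVKQELDYASKF
CPITADDECCTQKDEYIAFGHIKSTKTSVSEDRLETPAAVFRYRQESVEEDPHVFPFDSG
AESTTCTNDYGFQTICSVLVRSVSQPGHLFKNFFPKPPLKPCCRSDHNRVRRQTTKEFHD
ATCQYIQKNKFDPKLRFEIPKARAKNFASP
>AbdB_synthetic synthetic stand-in Hox protein
MCVYKKGAKPIVSERFIYFAPPSYGKYIKVPTFQPVYLPRSPARVRCNEPPDCKCAYHFK
RKASAPASENAYTADDPLTAPSHYYEGLVFTDGQHFIFHCFSSFKVEHKICTFCFSPADL
SKDEHFEREDATKFRHRVKQEPIEAGPHDTQYLTFNLKYSHIFVGHTQKDEHTNDFSIGI
CTYCDKYALCTLSHCLETPAALPEEEPPSNLVFVADIHGGPDTFNDSGAESHQQRAHQEI
LQPKRHDPRSVSQPSTNYTNTEIYNNTYDR
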