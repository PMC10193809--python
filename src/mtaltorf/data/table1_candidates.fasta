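>IP_306387 approach=OpenProt length=172aa host=nd2 relation=sense_frameshift position=4547-5063
IFYLSRPRNKHASFYSSSNQKNKPSFHRSCHQVFPHASNRIHNPSNSYPLQQYTLRTMNH
NQYYQSMLIINNHNSYSNKTRNSPLSLLSPRGYPRHPSDIRPASSHMTKTSPHLNHMPNL
SLTKRKPSPHSLNLIHHSRQLRWIKPNPATQNLSMLLNYPHRMNNSSSTVQP
>IP_306389 approach=OpenProt length=259aa host=cox1 relation=sense_frameshift position=6089-6866
ICNNLLHSNTHHNRRLWQLTSSPNNRCPRYGVSPHKQHKLLTLTSLSPTPARICYSGGRS
RNRLNSLPSLSRELLPPWSLRRPNHLLLTPSRCLLYLRGHQFHHNNYQYKTPCHNPMPNA
PLRLIRPNHSSPTSPISPSPSCWHHYTTNRPQPQHHLLRPRRRRRPHSMPTPILIFRSPW
SLYSYPTRLRNNLPYCNLLLRKKRTIWMHRYGLSYDINWLPRVYRVSTPYIYSRNRRRHT
SMFHLRYHNHRYPHRRQSI
>IP_306398 approach=OpenProt length=35aa host=nd4 relation=sense_frameshift position=11115-11219
MSSSKPHLSPPWLSSPDEATSQNAWTQAHTSYSTP
>IP_306403 approach=OpenProt length=49aa host=cytb relation=sense_frameshift position=14970-15116
MAESSATFTPMAPQYSLSASSYTSGEAYITDHFSTQKPETSALSSCLQL
>MS_cox3_antisense approach=MS length=95aa host=cox3 relation=antisense position=9462-9177
MGLSRIEGLFGQVVCGGLGMCFLVLHRAIIGMWLVCWLVGLVWGALWSGSEITWLGRRSL
GGLRGPLLGVMGWVLLYDRHVIGGSLCVVVQVEAY
>MS_cox1_antisense approach=MS length=73aa host=cox1 relation=antisense position=6061-5842
MWSLPRRLPGWPSSARMRRLRAVPRTPAHAPNNRYSVPMSLWFVENSQRSANISGGEVKW
LSEALDCKSKDRG
>MS_nd4_antisense approach=MS length=57aa host=nd4 relation=antisense position=11709-11535
IMRMTAPVKLQGVWMRMAVTTRAMWLIEEYAMSDFRSVCRRQMELVMIMPHRDSTRKG
>MTALTND4 approach=MS length=99aa host=nd4 relation=sense_frameshift position=11557-11854
MRHNYNKLHLPTTNRPKIAHCMLFNQPHSPRSNSHSHPNPLKLHRRSHSHNRPRAYILIT
ILPSKLKLRTHSQSHHNPLSRTSNSTPTNSFLMTSSKPR
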