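district,city
Zhongzheng,Taipei City
Datong,Taipei City
Zhongshan,Taipei City
Songshan,Taipei City
Daan,Taipei City
Wanhua,Taipei City
Xinyi,Taipei City
Shilin,Taipei City
Beitou,Taipei City
Neihu,Taipei City
Nangang,Taipei City
Wenshan,Taipei City
Banqiao,New Taipei City
Sanchong,New Taipei City
Zhonghe,New Taipei City
Yonghe,New Taipei City
Xinzhuang,New Taipei City
Xindian,New Taipei City
Tucheng,New Taipei City
Luzhou,New Taipei City
Shulin,New Taipei City
Xizhi,New Taipei City
Yingge,New Taipei City
Sanxia,New Taipei City
Danshui,New Taipei City
Ruifang,New Taipei City
Wugu,New Taipei City
Taishan,New Taipei City
Linkou,New Taipei City
Shenkeng,New Taipei City
Shiding,New Taipei City
Pinglin,New Taipei City
Sanzhi,New Taipei City
Shimen,New Taipei City
Bali,New Taipei City
Pingxi,New Taipei City
Shuangxi,New Taipei City
Gongliao,New Taipei City
Jinshan,New Taipei City
Wanli,New Taipei City
Wulai,New Taipei City
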